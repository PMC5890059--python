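"""Association models vs closed-form oracles; robust variances; stratification."""
import numpy as np
import pandas as pd
import pytest

from ironmr.association import (
    geometric_mean_ratio,
    iv_ratio_estimate,
    linear_association,
    logistic_association,
    per_allele_associations,
    stratified_analysis,
)
from ironmr.cohort import CohortConfig, generate_cohort
from ironmr.exceptions import CollinearityError, DegenerateInputError
from ironmr.genotypes import GenotypeMatrix


class TestLinear:
    def test_four_point_hand_dataset(self):
        data = pd.DataFrame({"x": [0, 1, 2, 3], "y": [1, 2, 2, 4]})
        res = linear_association(data, "y", "x")
        assert res.effect == pytest.approx(0.9)
        assert res.scale == "beta"
        assert res.ci_low <= res.effect <= res.ci_high

    def test_matches_normal_equations_oracle_with_covariates(self):
        rng = np.random.default_rng(37)
        n = 40
        data = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "c1": rng.normal(size=n),
                "c2": rng.normal(size=n),
            }
        )
        data["y"] = 0.5 * data.x - 0.2 * data.c1 + rng.normal(size=n)
        res = linear_association(data, "y", "x", ["c1", "c2"])
        X = np.column_stack([np.ones(n), data[["x", "c1", "c2"]].to_numpy()])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ data.y.to_numpy())
        resid = data.y.to_numpy() - X @ beta_hat
        sigma2 = resid @ resid / (n - 4)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        assert res.effect == pytest.approx(beta_hat[1], abs=1e-8)
        assert res.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-8)

    def test_collinear_covariate_named(self):
        rng = np.random.default_rng(41)
        data = pd.DataFrame({"x": rng.normal(size=30)})
        data["dup"] = 2 * data.x
        data["y"] = rng.normal(size=30)
        with pytest.raises(CollinearityError, match="dup"):
            linear_association(data, "y", "x", ["dup"])

    def test_score_fev1_beta_negative_under_causal_effect(self):
        # strong causal effect, no supplementation dilution: unambiguous sign
        cfg = CohortConfig(n_mothers=5000, causal_effect=1.0, gamma_supp=0.0,
                           supp_restore=0.0, seed=57)
        sc = generate_cohort(cfg)
        data = sc.cohort.copy()
        data["score"] = sc.score("iron").standardized
        res = linear_association(data, "fev1_sd", "score")
        assert res.effect < 0  # higher score -> lower iron -> lower lung function
        assert res.p_trend < 0.01


class TestLogistic:
    def test_two_by_two_table_odds_ratio(self):
        # exposure 1: 20 cases / 80 controls; exposure 0: 10 cases / 90 controls
        data = pd.DataFrame(
            {
                "y": [1] * 20 + [0] * 80 + [1] * 10 + [0] * 90,
                "x": [1] * 100 + [0] * 100,
            }
        )
        res = logistic_association(data, "y", "x")
        assert res.effect == pytest.approx((20 * 90) / (80 * 10), rel=1e-6)
        assert res.scale == "or"

    def test_constant_exposure_rejected(self):
        data = pd.DataFrame({"y": [0, 1] * 20, "x": [1.0] * 40})
        with pytest.raises(DegenerateInputError, match="constant"):
            logistic_association(data, "y", "x")

    def test_or_ci_covers_null_generator(self):
        covered = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(6000 + rep)
            data = pd.DataFrame(
                {"y": rng.binomial(1, 0.3, 400), "x": rng.normal(size=400)}
            )
            res = logistic_association(data, "y", "x")
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered / reps >= 0.85


class TestGeometricMeanRatio:
    def test_binary_exposure_equals_ratio_of_geometric_means(self):
        rng = np.random.default_rng(43)
        ige0 = np.exp(rng.normal(3.5, 1.0, 150))
        ige1 = np.exp(rng.normal(3.9, 1.2, 120))
        data = pd.DataFrame(
            {"ige": np.concatenate([ige0, ige1]),
             "x": np.r_[np.zeros(150), np.ones(120)]}
        )
        res = geometric_mean_ratio(data, "ige", "x")
        gm_ratio = np.exp(np.log(ige1).mean() - np.log(ige0).mean())
        assert res.effect == pytest.approx(gm_ratio, rel=1e-10)
        assert res.scale == "gmr"

    def test_nonpositive_ige_rejected(self):
        data = pd.DataFrame({"ige": [1.0, 0.0, 2.0], "x": [0, 1, 0]})
        with pytest.raises(ValueError, match="non-positive"):
            geometric_mean_ratio(data, "ige", "x")

    def test_robust_se_close_to_bootstrap(self):
        """Huber-White SE tracks a nonparametric bootstrap on skewed data."""
        rng = np.random.default_rng(47)
        n = 500
        x = rng.normal(size=n)
        # heteroscedastic: noise SD grows with |x|
        log_ige = 3.5 + 0.2 * x + rng.normal(size=n) * (0.5 + 0.8 * np.abs(x))
        data = pd.DataFrame({"ige": np.exp(log_ige), "x": x})
        res = geometric_mean_ratio(data, "ige", "x")
        boots = []
        for _ in range(500):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], log_ige[idx]
            xc = xb - xb.mean()
            boots.append((xc @ yb) / (xc @ xc))
        boot_se = np.std(boots, ddof=1)
        assert res.se == pytest.approx(boot_se, rel=0.10)


class TestPerAlleleAndStratified:
    def test_single_snp_consistent_with_linear(self, small_cohort):
        g = small_cohort.maternal_genotypes.subset_snps(["rs1800562"])
        data = small_cohort.cohort.copy()
        res = per_allele_associations(g, data, "fev1_sd")[0]
        data2 = data.copy()
        data2["rs1800562"] = g.dosage[:, 0]
        ref = linear_association(data2, "fev1_sd", "rs1800562")
        assert res.effect == pytest.approx(ref.effect, abs=1e-12)

    def test_twelve_snp_battery_has_twelve_rows(self, small_cohort):
        res = per_allele_associations(
            small_cohort.maternal_genotypes, small_cohort.cohort, "hb_late"
        )
        assert len(res) == 12
        assert [r.exposure for r in res] == small_cohort.maternal_genotypes.snp_ids

    def test_injected_per_allele_effect_recovered(self):
        rng = np.random.default_rng(53)
        n = 20_000
        dose = rng.binomial(2, 0.5, n).astype(float)
        hb = 12.0 - 0.1 * dose + rng.normal(0, 1.0, n)
        g = GenotypeMatrix([str(i) for i in range(n)], ["snp"], dose[:, None])
        data = pd.DataFrame({"hb": hb}, index=[str(i) for i in range(n)])
        res = per_allele_associations(g, data, "hb")[0]
        assert res.ci_low <= -0.1 <= res.ci_high

    def test_stratified_counts_sum_to_total(self, small_cohort):
        data = small_cohort.cohort.copy()
        data["score"] = small_cohort.score("iron").standardized
        res = stratified_analysis(data, ["score"], include_ige=False)
        fev = [r for r in res if r.outcome == "fev1_sd"]
        by_stratum = {r.stratum: r.n for r in fev}
        assert by_stratum["unsupplemented"] + by_stratum["supplemented"] == by_stratum["all"]

    def test_constant_stratifier_matches_unstratified_modulo_covariate(self, small_cohort):
        data = small_cohort.cohort.copy()
        data["score"] = small_cohort.score("iron").standardized
        data["supp_late"] = 0
        res = stratified_analysis(data, ["score"], include_ige=False)
        # supp_late constant -> dropped from the overall model is impossible
        # (collinear with intercept); the stratum-0 fit is the reference
        unsupp = [r for r in res if r.stratum == "unsupplemented" and r.outcome == "fev1_sd"][0]
        plain = linear_association(data, "fev1_sd", "score")
        assert unsupp.effect == pytest.approx(plain.effect, abs=1e-12)


def test_iv_ratio_matches_manual_wald(small_cohort):
    data = pd.DataFrame(
        {
            "y": small_cohort.cohort["fev1_sd"].to_numpy(),
            "x": small_cohort.post_supp_iron,
            "z": small_cohort.score("iron").standardized,
        }
    )
    r = iv_ratio_estimate(data, "y", "x", "z")
    assert r["estimate"] == pytest.approx(r["beta_outcome"] / r["beta_exposure"])
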