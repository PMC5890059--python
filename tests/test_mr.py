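"""Summary-data MR estimators against closed-form and brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ironmr.association import AssociationResult
from ironmr.exceptions import DegenerateInputError
from ironmr.mr import (
    MRSummaryData,
    _weighted_median,
    assemble_mr_summary,
    ivw_estimate,
    mr_egger,
    weighted_median,
)

TOY = MRSummaryData(
    ("s1", "s2", "s3"),
    np.array([0.1, 0.2, 0.3]),
    np.array([0.02, 0.05, 0.06]),
    np.array([0.01, 0.01, 0.02]),
)


def _wls_oracle(bx, by, se, intercept):
    """Weighted least squares via normal equations (independent oracle)."""
    w = 1.0 / se**2
    X = np.column_stack([np.ones_like(bx), bx]) if intercept else bx[:, None]
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    theta = cov @ (XtW @ by)
    return theta, np.sqrt(np.diag(cov))


class TestIvw:
    def test_single_snp_is_wald_ratio(self):
        d = MRSummaryData(("s1",), np.array([0.2]), np.array([0.05]), np.array([0.01]))
        assert ivw_estimate(d).slope == pytest.approx(0.25)

    def test_equal_ratios_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.4])
        d = MRSummaryData(("a", "b", "c"), bx, 0.7 * bx, np.array([0.01, 0.02, 0.01]))
        assert ivw_estimate(d).slope == pytest.approx(0.7, abs=1e-14)

    def test_three_snp_toy_matches_wls_oracle(self):
        est = ivw_estimate(TOY)
        theta, ses = _wls_oracle(TOY.beta_exposure, TOY.beta_outcome, TOY.se_outcome, False)
        assert est.slope == pytest.approx(theta[0], abs=1e-12)
        assert est.slope_se == pytest.approx(ses[0], abs=1e-12)

    def test_zero_exposure_betas_rejected(self):
        d = MRSummaryData(("a", "b"), np.zeros(2), np.array([0.1, 0.2]), np.array([0.1, 0.1]))
        with pytest.raises(DegenerateInputError):
            ivw_estimate(d)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        d = MRSummaryData(("a", "b", "c", "d"), bx, 0.5 * bx, np.full(4, 0.02))
        est = mr_egger(d)
        assert est.slope == pytest.approx(0.5, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_pleiotropy_absorbed_by_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        d0 = MRSummaryData(tuple("abcde"), bx, 0.4 * bx, np.full(5, 0.02))
        d1 = MRSummaryData(tuple("abcde"), bx, 0.4 * bx + 0.03, np.full(5, 0.02))
        e0, e1 = mr_egger(d0), mr_egger(d1)
        assert e1.intercept == pytest.approx(0.03, abs=1e-12)
        assert e1.slope == pytest.approx(e0.slope, abs=1e-12)

    def test_matches_wls_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            k = rng.integers(3, 11)
            bx = rng.uniform(0.01, 0.5, k)
            by = rng.normal(0, 0.1, k)
            se = rng.uniform(0.005, 0.05, k)
            d = MRSummaryData(tuple(f"s{i}" for i in range(k)), bx, by, se)
            est = mr_egger(d)
            theta, ses = _wls_oracle(bx, by, se, True)
            assert est.intercept == pytest.approx(theta[0], abs=1e-10)
            assert est.slope == pytest.approx(theta[1], abs=1e-10)
            assert est.slope_se == pytest.approx(ses[1], abs=1e-10)

    def test_fewer_than_three_snps_rejected(self):
        d = MRSummaryData(("a", "b"), np.array([0.1, 0.2]), np.array([0.0, 0.1]),
                          np.array([0.01, 0.01]))
        with pytest.raises(ValueError, match=">= 3"):
            mr_egger(d)

    def test_zero_intercept_constraint_reproduces_ivw(self):
        """Egger's design matrix without the intercept column IS the IVW fit."""
        rng = np.random.default_rng(67)
        for _ in range(10):
            k = rng.integers(2, 11)
            bx = rng.uniform(0.01, 0.5, k)
            by = rng.normal(0, 0.1, k)
            se = rng.uniform(0.005, 0.05, k)
            d = MRSummaryData(tuple(f"s{i}" for i in range(k)), bx, by, se)
            ivw = ivw_estimate(d)
            theta, ses = _wls_oracle(bx, by, se, False)
            assert ivw.slope == pytest.approx(theta[0], abs=1e-14)
            assert ivw.slope_se == pytest.approx(ses[0], abs=1e-14)


class TestWeightedMedian:
    def test_equal_ratios_give_that_ratio(self):
        bx = np.array([0.1, 0.2, 0.3])
        d = MRSummaryData(("a", "b", "c"), bx, 2.0 * bx, np.array([0.01, 0.03, 0.02]))
        est = weighted_median(d, n_boot=100, seed=0)
        assert est.slope == pytest.approx(2.0, abs=1e-12)

    def test_equal_weights_interpolation_is_median(self):
        assert _weighted_median(np.array([1.0, 2.0, 9.0]), np.ones(3)) == pytest.approx(2.0)

    def test_interpolation_formula_brute_force(self):
        """Frozen evaluations of the midpoint-interpolation convention."""
        r = np.array([1.0, 3.0])
        w = np.array([1.0, 1.0])
        # midpoints 0.25, 0.75 -> 0.5 interpolates halfway: 2.0
        assert _weighted_median(r, w) == pytest.approx(2.0)
        # weight 3:1 -> midpoints 0.375, 0.875; 0.5 -> 1 + (0.125/0.5)*2 = 1.5
        assert _weighted_median(r, np.array([3.0, 1.0])) == pytest.approx(1.5)

    def test_robust_to_minority_invalid_instruments(self):
        """6 valid SNPs (ratio c) + 4 pleiotropic: WM ~ c while IVW is biased."""
        rng = np.random.default_rng(71)
        c = 0.3
        bx = rng.uniform(0.1, 0.4, 10)
        by = c * bx
        by[6:] += 0.25  # large directional pleiotropy on 4 of 10
        se = np.full(10, 0.01)
        d = MRSummaryData(tuple(f"s{i}" for i in range(10)), bx, by, se)
        wm = weighted_median(d, n_boot=500, seed=1)
        ivw = ivw_estimate(d)
        assert wm.slope == pytest.approx(c, abs=3 * wm.slope_se + 0.02)
        assert abs(ivw.slope - c) > 5 * abs(wm.slope - c) or abs(ivw.slope - c) > 0.1

    def test_seeded_bootstrap_reproducible(self):
        a = weighted_median(TOY, n_boot=300, seed=5)
        b = weighted_median(TOY, n_boot=300, seed=5)
        assert a.slope_se == b.slope_se

    def test_zero_exposure_beta_rejected(self):
        d = MRSummaryData(("a", "b"), np.array([0.0, 0.2]), np.array([0.0, 0.1]),
                          np.array([0.01, 0.01]))
        with pytest.raises(DegenerateInputError):
            weighted_median(d, n_boot=10, seed=0)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(TOY, n_boot=10)


class TestAssembleAndInvariance:
    def _per_allele(self, table, biomarker, slope=0.5):
        out = []
        for snp, bx in table.effects_for_biomarker(biomarker).items():
            out.append(
                AssociationResult(
                    outcome="fev1_sd", exposure=snp, n=100, effect=slope * bx,
                    scale="beta", se=0.02, ci_low=slope * bx - 0.05,
                    ci_high=slope * bx + 0.05, p_trend=0.5,
                )
            )
        return out

    def test_iron_summary_has_five_rows_oriented_positive(self, table):
        d = assemble_mr_summary(table, self._per_allele(table, "iron"), "iron")
        assert len(d) == 5
        assert np.all(d.beta_exposure >= 0)

    def test_missing_per_allele_snp_is_error(self, table):
        per = self._per_allele(table, "iron")[1:]
        with pytest.raises(KeyError, match="rs1799945"):
            assemble_mr_summary(table, per, "iron")

    @settings(max_examples=25, deadline=None)
    @given(flips=st.lists(st.booleans(), min_size=4, max_size=4))
    def test_joint_sign_flips_leave_estimates_invariant(self, flips):
        bx = np.array([0.1, 0.25, 0.3, 0.15])
        by = np.array([0.02, 0.07, 0.05, 0.01])
        se = np.array([0.01, 0.02, 0.015, 0.01])
        sign = np.where(np.array(flips), -1.0, 1.0)
        d0 = MRSummaryData(tuple("abcd"), bx, by, se)
        d1 = MRSummaryData(tuple("abcd"), bx * sign, by * sign, se)
        assert ivw_estimate(d1).slope == pytest.approx(ivw_estimate(d0).slope, abs=1e-14)
        e0 = mr_egger(d0.oriented_positive())
        e1 = mr_egger(d1.oriented_positive())
        assert e1.slope == pytest.approx(e0.slope, abs=1e-14)
        assert e1.intercept == pytest.approx(e0.intercept, abs=1e-14)
        w0 = weighted_median(d0, n_boot=200, seed=9)
        w1 = weighted_median(d1, n_boot=200, seed=9)
        assert w1.slope == pytest.approx(w0.slope, abs=1e-14)

    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "summary.tsv"
        TOY.to_tsv(p)
        back = MRSummaryData.from_tsv(p)
        np.testing.assert_allclose(back.beta_exposure, TOY.beta_exposure)
        np.testing.assert_allclose(back.beta_outcome, TOY.beta_outcome)
        assert back.snp_ids == TOY.snp_ids
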