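"""Instrument validation: Hardy-Weinberg tests, LD screen, proxy check.

Before a genotypic score is trusted as an instrumental variable it is
screened three ways: each SNP is tested for Hardy-Weinberg equilibrium with
a likelihood-ratio test; pairwise linkage disequilibrium between the loci is
screened as the squared dosage correlation (composite LD — phase-free, which
is all a correlation screen needs); and the scores are validated against the
measurable proxy of iron status, maternal haemoglobin, overall and within
supplementation strata.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .scores import RiskScore
from ._stats import simple_ols

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HweResult:
    """Likelihood-ratio test of Hardy-Weinberg equilibrium at one SNP."""

    snp_id: str
    counts: tuple[int, int, int]  # (n_AA, n_Aa, n_aa), a = counted allele
    lrt_stat: float
    p_value: float
    monomorphic: bool = False


def hwe_lrt(counts: tuple[int, int, int], snp_id: str = "") -> HweResult:
    """HWE likelihood-ratio test from genotype counts.

    The saturated multinomial likelihood (observed genotype proportions) is
    compared with the HWE-constrained likelihood evaluated at the MLE allele
    frequency p̂ = (2 n_aa + n_Aa) / 2n; the statistic
    2·[ℓ_sat − ℓ_HWE] is referred to chi-square with 1 df.  A monomorphic
    SNP is in HWE by definition (stat 0, p 1, flagged).
    """
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")

    p_hat = (2 * n_aa + n_Aa) / (2 * n)
    if p_hat in (0.0, 1.0):
        return HweResult(snp_id, (n_AA, n_Aa, n_aa), 0.0, 1.0, monomorphic=True)

    expected = n * np.array([(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    mask = observed > 0
    stat = 2.0 * float(np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))
    stat = max(stat, 0.0)  # guard tiny negative round-off
    p = float(stats.chi2.sf(stat, df=1))
    return HweResult(snp_id, (n_AA, n_Aa, n_aa), stat, p)


def hwe_test_matrix(genotypes: GenotypeMatrix) -> list[HweResult]:
    """HWE LRT per SNP of an integer-dosage matrix (missing calls skipped)."""
    results = []
    for snp in genotypes.snp_ids:
        d = genotypes.column(snp)
        d = d[~np.isnan(d)]
        if not np.all(d == np.round(d)):
            raise ValueError(f"{snp}: HWE test requires hard genotype calls")
        counts = (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
        results.append(hwe_lrt(counts, snp_id=snp))
    return results


def pairwise_ld_r2(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Composite LD: squared Pearson correlation of dosage columns.

    Missing dosages are handled pairwise-complete.  Zero-variance columns
    yield NaN entries (with a warning); the diagonal is 1 for polymorphic
    SNPs.
    """
    if genotypes.n_snps < 2 or genotypes.n_individuals < 2:
        raise ValueError("need >= 2 SNPs and >= 2 individuals for an LD screen")
    df = genotypes.to_frame()
    r2 = df.corr(method="pearson", min_periods=2) ** 2
    variances = df.var()
    degenerate = variances[variances == 0].index.tolist()
    if degenerate:
        warnings.warn(
            f"zero-variance SNP column(s), r^2 undefined: {degenerate}",
            RuntimeWarning,
            stacklevel=2,
        )
        r2.loc[degenerate, :] = np.nan
        r2.loc[:, degenerate] = np.nan
    poly = [s for s in df.columns if s not in degenerate]
    for s in poly:
        r2.loc[s, s] = 1.0
    return r2


def proxy_validation(
    score: RiskScore,
    cohort: pd.DataFrame,
    stratify_by_supp: bool = True,
    min_stratum_size: int = 10,
) -> pd.DataFrame:
    """Regress haemoglobin (g/dL) on the standardized score, per stratum.

    Returns one row per (haemoglobin timing, stratum): overall, and — if
    requested — within late-pregnancy supplementation strata.  Strata with
    fewer than ``min_stratum_size`` records are skipped with a warning.
    The slope is g/dL per SD of genotypic score; a valid instrument for low
    iron status shows a negative slope.
    """
    data = cohort.loc[score.individual_ids].copy()
    data["_score"] = score.standardized

    strata: list[tuple[str, pd.DataFrame]] = [("all", data)]
    if stratify_by_supp:
        strata.append(("unsupplemented", data[data["supp_late"] == 0]))
        strata.append(("supplemented", data[data["supp_late"] == 1]))

    rows = []
    for hb_col in ("hb_early", "hb_late"):
        if hb_col not in data.columns:
            continue
        for label, sub in strata:
            sub = sub.dropna(subset=[hb_col])
            if len(sub) < min_stratum_size:
                logger.warning("stratum %r has %d records (<%d); skipped",
                               label, len(sub), min_stratum_size)
                continue
            beta, se, p = simple_ols(sub[hb_col].to_numpy(), sub["_score"].to_numpy())
            zcrit = stats.t.ppf(0.975, df=len(sub) - 2)
            rows.append(
                {
                    "stratum": label,
                    "exposure": f"{score.biomarker}_score",
                    "haemoglobin": hb_col,
                    "n": len(sub),
                    "beta": beta,
                    "se": se,
                    "ci_low": beta - zcrit * se,
                    "ci_high": beta + zcrit * se,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
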