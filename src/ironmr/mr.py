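"""Summary-data Mendelian randomisation estimators.

Implements the three standard summary-data MR estimators from their
formulas:

* **IVW** — inverse-variance weighted regression of per-SNP outcome
  associations on exposure associations through the origin, with
  first-order weights w_j = 1/se_yj² :
  slope = Σ w β_x β_y / Σ w β_x²,  se = sqrt(1 / Σ w β_x²).
* **MR-Egger** — the same weighted regression with an unconstrained
  intercept; a non-zero intercept estimates average directional pleiotropy
  (under the InSIDE assumption) and the slope remains a causal estimate.
* **Weighted median** — the weighted median of the per-SNP Wald ratios
  r_j = β_yj/β_xj with weights β_xj²/se_yj²; consistent when at least half
  the weight comes from valid instruments.  SE by seeded parametric
  bootstrap.

Standard errors for IVW and Egger use the fixed-effect weighted
least-squares covariance (X'WX)⁻¹ (no residual-dispersion scaling), so
Egger with its intercept constrained to zero reproduces IVW exactly.
First-order weights are used throughout because the exposure betas come
from a published meta-analysis that prints no standard errors.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult
from .exceptions import DegenerateInputError
from .weights import SnpWeightTable, _check_biomarker

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MRSummaryData:
    """Harmonised per-SNP summary statistics for one exposure-outcome pair."""

    snp_ids: tuple[str, ...]
    beta_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray

    def __post_init__(self) -> None:
        bx = np.asarray(self.beta_exposure, dtype=float)
        by = np.asarray(self.beta_outcome, dtype=float)
        se = np.asarray(self.se_outcome, dtype=float)
        object.__setattr__(self, "beta_exposure", bx)
        object.__setattr__(self, "beta_outcome", by)
        object.__setattr__(self, "se_outcome", se)
        k = len(self.snp_ids)
        if k == 0:
            raise ValueError("need at least one SNP")
        if len(set(self.snp_ids)) != k:
            raise ValueError("duplicate SNPs in summary data")
        if not (len(bx) == len(by) == len(se) == k):
            raise ValueError("summary-data arrays have inconsistent lengths")
        if not (np.isfinite(bx).all() and np.isfinite(by).all() and np.isfinite(se).all()):
            raise ValueError("summary data contain non-finite values")
        if np.any(se <= 0):
            raise ValueError("outcome SEs must be positive")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def oriented_positive(self) -> "MRSummaryData":
        """Flip SNPs so every beta_exposure is non-negative (Egger requires it)."""
        sign = np.where(self.beta_exposure < 0, -1.0, 1.0)
        return MRSummaryData(
            self.snp_ids, self.beta_exposure * sign, self.beta_outcome * sign, self.se_outcome
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta_exposure": self.beta_exposure,
                "beta_outcome": self.beta_outcome,
                "se_outcome": self.se_outcome,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MRSummaryData":
        df = pd.read_csv(path, sep="\t")
        return cls(
            tuple(df["snp_id"].astype(str)),
            df["beta_exposure"].to_numpy(),
            df["beta_outcome"].to_numpy(),
            df["se_outcome"].to_numpy(),
        )


@dataclass(frozen=True)
class MREstimate:
    """A causal-slope estimate from one summary-data MR method."""

    method: str  # ivw | egger | weighted_median
    slope: float
    slope_se: float
    ci_low: float
    ci_high: float
    p: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        if (self.method == "egger") != (self.intercept is not None):
            raise ValueError("intercept present iff method is egger")
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("CI does not bracket the slope")


def assemble_mr_summary(
    table: SnpWeightTable,
    per_allele: Sequence[AssociationResult],
    biomarker: str,
) -> MRSummaryData:
    """Pair each selected SNP's exposure beta with its outcome beta/SE.

    ``per_allele`` must be oriented to the same risk alleles as the weight
    table for this biomarker.  The result is oriented so all exposure betas
    are non-negative (per-SNP joint sign flips, which leave every estimator
    invariant).
    """
    _check_biomarker(biomarker)
    by_snp = {}
    for r in per_allele:
        if r.scale == "beta":
            by_snp[r.exposure] = (r.effect, r.se)
        else:  # OR scale: use the log-odds beta and its SE
            by_snp[r.exposure] = (float(np.log(r.effect)), r.se)
    snps = table.select_snps_for_biomarker(biomarker)
    missing = [s for s in snps if s not in by_snp]
    if missing:
        raise KeyError(f"per-allele outcome results missing for SNP(s): {missing}")
    effects = table.effects_for_biomarker(biomarker)
    bx = np.array([effects[s] for s in snps])
    by = np.array([by_snp[s][0] for s in snps])
    se = np.array([by_snp[s][1] for s in snps])
    return MRSummaryData(tuple(snps), bx, by, se).oriented_positive()


def ivw_estimate(data: MRSummaryData) -> MREstimate:
    """Fixed-effect inverse-variance weighted estimate.

    With a single SNP this reduces to the Wald ratio β_y/β_x.
    """
    w = 1.0 / data.se_outcome**2
    denom = float(np.sum(w * data.beta_exposure**2))
    if denom == 0.0:
        raise DegenerateInputError("all exposure betas are zero; IVW undefined")
    slope = float(np.sum(w * data.beta_exposure * data.beta_outcome)) / denom
    se = float(np.sqrt(1.0 / denom))
    p = 2.0 * float(stats.norm.sf(abs(slope / se)))
    return MREstimate(
        method="ivw",
        slope=slope,
        slope_se=se,
        ci_low=slope - _Z95 * se,
        ci_high=slope + _Z95 * se,
        p=p,
    )


def mr_egger(data: MRSummaryData) -> MREstimate:
    """MR-Egger regression (weighted, unconstrained intercept).

    Requires >= 3 SNPs and non-negative exposure betas (use
    :meth:`MRSummaryData.oriented_positive`).
    """
    if len(data) < 3:
        raise ValueError("MR-Egger needs >= 3 SNPs for useful inference")
    if np.any(data.beta_exposure < 0):
        raise ValueError("MR-Egger requires beta_exposure oriented non-negative")
    w = 1.0 / data.se_outcome**2
    X = np.column_stack([np.ones(len(data)), data.beta_exposure])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    theta = cov @ (XtW @ data.beta_outcome)
    intercept, slope = (float(t) for t in theta)
    se_int, se_slope = (float(s) for s in np.sqrt(np.diag(cov)))
    p = 2.0 * float(stats.norm.sf(abs(slope / se_slope)))
    p_int = 2.0 * float(stats.norm.sf(abs(intercept / se_int)))
    return MREstimate(
        method="egger",
        slope=slope,
        slope_se=se_slope,
        ci_low=slope - _Z95 * se_slope,
        ci_high=slope + _Z95 * se_slope,
        p=p,
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=p_int,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with the midpoint convention.

    Sort ratios ascending; at cumulative standardized weight
    s_j = (Σ_{k<=j} w_k) − w_j/2, linearly interpolate the sorted ratios at
    s = 0.5 (clamped to the end ratios outside the midpoint range).
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def _weighted_median_many(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians (same convention as :func:`_weighted_median`).

    Vectorised over the first axis for the parametric bootstrap.
    """
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = weights[order] / weights.sum()
    s = np.cumsum(w, axis=1) - w / 2.0
    k = s.shape[1]
    # index of first midpoint >= 0.5 per row; clamp to the end ratios outside
    j = (s < 0.5).sum(axis=1)
    out = np.empty(len(ratios))
    lo_edge = j == 0
    hi_edge = j == k
    out[lo_edge] = r[lo_edge, 0]
    out[hi_edge] = r[hi_edge, -1]
    mid = ~(lo_edge | hi_edge)
    rows = np.flatnonzero(mid)
    jm = j[mid]
    s0, s1 = s[rows, jm - 1], s[rows, jm]
    r0, r1 = r[rows, jm - 1], r[rows, jm]
    frac = np.where(s1 > s0, (0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0)
    out[mid] = r0 + frac * (r1 - r0)
    return out


def weighted_median(data: MRSummaryData, n_boot: int = 2000, seed: int | None = None) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP Wald ratios r_j = β_yj/β_xj are combined with weights
    β_xj²/se_yj² (inverse variance of the ratio, first order).  The SE is
    the SD of the estimate over ``n_boot`` re-draws β_yj* ~ N(β_yj, se_yj);
    a seed is mandatory for reproducibility.
    """
    if len(data) < 2:
        raise ValueError("weighted median needs >= 2 SNPs")
    if np.any(data.beta_exposure == 0):
        raise DegenerateInputError("beta_exposure contains zeros; Wald ratios undefined")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    ratios = data.beta_outcome / data.beta_exposure
    weights = data.beta_exposure**2 / data.se_outcome**2
    est = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    by_boot = rng.normal(data.beta_outcome, data.se_outcome, size=(n_boot, len(data)))
    boot = _weighted_median_many(by_boot / data.beta_exposure, weights)
    se = float(boot.std(ddof=1))
    if se == 0.0:
        p = 0.0 if est != 0 else 1.0
    else:
        p = 2.0 * float(stats.norm.sf(abs(est / se)))
    return MREstimate(
        method="weighted_median",
        slope=est,
        slope_se=se,
        ci_low=est - _Z95 * se,
        ci_high=est + _Z95 * se,
        p=p,
    )


def all_estimates(
    data: MRSummaryData, n_boot: int = 2000, seed: int | None = 0
) -> list[MREstimate]:
    """IVW, Egger (if >= 3 SNPs) and weighted median (if >= 2 SNPs)."""
    out = [ivw_estimate(data)]
    if len(data) >= 3:
        out.append(mr_egger(data.oriented_positive()))
    if len(data) >= 2:
        out.append(weighted_median(data, n_boot=n_boot, seed=seed))
    return out


def estimates_to_frame(estimates: Sequence[MREstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "method": e.method,
                "slope": e.slope,
                "slope_se": e.slope_se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p": e.p,
                "intercept": e.intercept if e.intercept is not None else np.nan,
                "intercept_se": e.intercept_se if e.intercept_se is not None else np.nan,
                "intercept_p": e.intercept_p if e.intercept_p is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
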