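"""Score-outcome and per-allele association models.

One-sample analyses of genotypic scores (per SD) and individual SNPs (per
risk allele) against continuous outcomes (SD units; ordinary least squares),
binary outcomes (logistic regression, odds ratios), and total IgE
(geometric-mean ratios from a log-linear model with heteroscedasticity-
robust Huber-White variances).  Two-sided tests at alpha = 0.05 throughout;
no multiple-testing correction is applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning
import warnings

from .exceptions import CollinearityError, DegenerateInputError, SeparationError
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class AssociationResult:
    """One fitted exposure-outcome association on its reporting scale.

    ``scale`` is ``beta`` (difference per unit exposure), ``or`` (odds
    ratio) or ``gmr`` (geometric-mean ratio); for the latter two the CI is
    symmetric on the log scale and exponentiated for reporting.
    """

    outcome: str
    exposure: str
    n: int
    effect: float
    scale: str  # beta | or | gmr
    se: float  # on the estimation (link) scale
    ci_low: float
    ci_high: float
    p_trend: float
    covariates: tuple[str, ...] = ()
    stratum: str = "all"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.effect <= self.ci_high):
            raise ValueError("CI does not bracket the effect estimate")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = ",".join(self.covariates)
        return d


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def _design(
    data: pd.DataFrame, exposure: str, covariates: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    cols = [exposure, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"column(s) not in data: {missing}")
    clean = data.dropna(subset=cols)
    X = sm.add_constant(clean[cols].astype(float), has_constant="add")
    _check_full_rank(X)
    return clean, X


def _check_full_rank(X: pd.DataFrame) -> None:
    """Raise CollinearityError naming the first aliased column."""
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return
    rank = 0
    for j, col in enumerate(X.columns):
        new_rank = np.linalg.matrix_rank(arr[:, : j + 1])
        if new_rank == rank:
            raise CollinearityError(str(col))
        rank = new_rank
    raise CollinearityError(str(X.columns[-1]))  # pragma: no cover


def _wald_ci(beta: float, se: float, dist: stats.rv_continuous | None = None, df: int = 0):
    crit = stats.t.ppf(1 - ALPHA / 2, df) if df > 0 else stats.norm.ppf(1 - ALPHA / 2)
    return beta - crit * se, beta + crit * se


def linear_association(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    stratum: str = "all",
) -> AssociationResult:
    """OLS of a continuous outcome on the exposure plus covariates.

    Reports the exposure coefficient with a Wald t-interval and two-sided p.
    """
    clean, X = _design(data, exposure, covariates)
    model = sm.OLS(clean[outcome].astype(float), X)
    res = model.fit()
    beta = float(res.params[exposure])
    se = float(res.bse[exposure])
    dfres = int(res.df_resid)
    lo, hi = _wald_ci(beta, se, df=dfres)
    return AssociationResult(
        outcome=outcome,
        exposure=exposure,
        n=int(res.nobs),
        effect=beta,
        scale="beta",
        se=se,
        ci_low=lo,
        ci_high=hi,
        p_trend=float(res.pvalues[exposure]),
        covariates=tuple(covariates),
        stratum=stratum,
    )


def logistic_association(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    stratum: str = "all",
) -> AssociationResult:
    """Maximum-likelihood logistic regression; effect reported as an OR.

    Raises :class:`SeparationError` on complete or quasi-complete
    separation and :class:`DegenerateInputError` for a constant exposure.
    """
    if data.dropna(subset=[exposure])[exposure].nunique() < 2:
        raise DegenerateInputError(f"exposure {exposure!r} is constant; OR undefined")
    clean, X = _design(data, exposure, covariates)
    y = clean[outcome].astype(float)
    if y.nunique() < 2:
        raise DegenerateInputError(f"outcome {outcome!r} has a single class")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(
            f"logistic model for {outcome!r} is separated on {exposure!r}: {exc}"
        ) from exc
    beta = float(res.params[exposure])
    se = float(res.bse[exposure])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        raise SeparationError(
            f"logistic model for {outcome!r}: non-finite or exploding estimate "
            f"(beta={beta:.3g}, se={se:.3g}) — likely separation"
        )
    lo, hi = _wald_ci(beta, se)
    return AssociationResult(
        outcome=outcome,
        exposure=exposure,
        n=int(res.nobs),
        effect=float(np.exp(beta)),
        scale="or",
        se=se,
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p_trend=float(res.pvalues[exposure]),
        covariates=tuple(covariates),
        stratum=stratum,
    )


def geometric_mean_ratio(
    data: pd.DataFrame,
    ige_column: str,
    exposure: str,
    covariates: Sequence[str] = (),
    stratum: str = "all",
) -> AssociationResult:
    """Geometric-mean ratio of IgE per unit exposure.

    ln(IgE) is regressed on the exposure; exp(beta) is the ratio of
    geometric means per unit increase.  Confidence limits use
    heteroscedasticity-robust (Huber-White sandwich, HC1) variances, since
    IgE is strongly right-skewed even after the log transform.
    """
    cols = [ige_column, exposure, *covariates]
    clean = data.dropna(subset=[c for c in cols if c in data.columns])
    bad = clean.index[clean[ige_column] <= 0].tolist()
    if bad:
        raise ValueError(f"non-positive IgE for record(s): {bad[:10]}")
    clean = clean.assign(_log_ige=np.log(clean[ige_column].astype(float)))
    clean2, X = _design(clean, exposure, covariates)
    res = sm.OLS(clean2["_log_ige"], X).fit(cov_type="HC1")
    beta = float(res.params[exposure])
    se = float(res.bse[exposure])
    lo, hi = _wald_ci(beta, se)
    return AssociationResult(
        outcome=ige_column,
        exposure=exposure,
        n=int(res.nobs),
        effect=float(np.exp(beta)),
        scale="gmr",
        se=se,
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p_trend=float(res.pvalues[exposure]),
        covariates=tuple(covariates),
        stratum=stratum,
    )


def per_allele_associations(
    genotypes: GenotypeMatrix,
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = (),
    model: str = "linear",
    stratum: str = "all",
) -> list[AssociationResult]:
    """One regression per SNP with dosage as the linear (p-trend) term.

    Dosages must already be oriented to the risk alleles of the analysis
    biomarker.
    """
    fit = {"linear": linear_association, "logistic": logistic_association}[model]
    results = []
    frame = genotypes.to_frame()
    for snp in genotypes.snp_ids:
        merged = data.copy()
        merged[snp] = frame[snp].reindex(merged.index).to_numpy()
        results.append(fit(merged, outcome, snp, covariates, stratum=stratum))
    return results


#: (column, model) pairs of the standard offspring-outcome battery
OUTCOME_BATTERY: tuple[tuple[str, str], ...] = (
    ("atopy", "logistic"),
    ("asthma", "logistic"),
    ("fev1_sd", "linear"),
    ("fvc_sd", "linear"),
    ("fef2575_sd", "linear"),
)


def outcome_battery(
    data: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str] = (),
    stratum: str = "all",
    include_ige: bool = True,
) -> list[AssociationResult]:
    """Run the full outcome battery for one exposure in one stratum."""
    results = []
    for outcome, model in OUTCOME_BATTERY:
        if outcome not in data.columns:
            continue
        fit = linear_association if model == "linear" else logistic_association
        results.append(fit(data, outcome, exposure, covariates, stratum=stratum))
    if include_ige:
        if "ige" in data.columns:
            results.append(geometric_mean_ratio(data, "ige", exposure, covariates, stratum))
        elif "log_ige" in data.columns:
            tmp = data.assign(ige=np.exp(data["log_ige"]))
            results.append(geometric_mean_ratio(tmp, "ige", exposure, covariates, stratum))
    return results


def stratified_analysis(
    data: pd.DataFrame,
    exposures: Sequence[str],
    covariates: Sequence[str] = (),
    stratifier: str = "supp_late",
    supp_covariate: str = "supp_late",
    include_ige: bool = True,
) -> list[AssociationResult]:
    """Outcome battery overall and within each stratum of ``stratifier``.

    The unstratified pass additionally adjusts for supplementation (the
    stratified passes cannot, the stratifier being constant within stratum).
    """
    if data[stratifier].isna().any():
        raise ValueError(f"stratifier {stratifier!r} contains missing values")
    levels = sorted(data[stratifier].unique())
    if not set(levels) <= {0, 1}:
        raise ValueError(f"stratifier {stratifier!r} must be binary 0/1")
    results: list[AssociationResult] = []
    overall_covs = list(covariates)
    if (
        supp_covariate
        and supp_covariate in data.columns
        and supp_covariate not in overall_covs
        and data[supp_covariate].nunique() > 1  # constant covariate aliases the intercept
    ):
        overall_covs.append(supp_covariate)
    for exposure in exposures:
        results += outcome_battery(data, exposure, overall_covs, "all", include_ige)
        for level in levels:
            sub = data[data[stratifier] == level]
            if len(sub) == 0:
                raise ValueError(f"empty stratum {stratifier}={level}")
            label = {0: "unsupplemented", 1: "supplemented"}.get(int(level), str(level))
            results += outcome_battery(sub, exposure, list(covariates), label, include_ige)
    return results


def iv_ratio_estimate(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    instrument: str,
) -> dict[str, float]:
    """One-sample Wald ratio: (outcome ~ Z) / (exposure ~ Z).

    The standard single-instrument IV estimator; SE by the first-order delta
    method (exposure-association uncertainty ignored, as is conventional
    when the instrument-exposure association is strong).
    """
    from ._stats import simple_ols

    z = data[instrument].to_numpy(dtype=float)
    by, se_y, _ = simple_ols(data[outcome].to_numpy(dtype=float), z)
    bx, _, _ = simple_ols(data[exposure].to_numpy(dtype=float), z)
    if bx == 0.0:
        raise DegenerateInputError("instrument-exposure association is exactly zero")
    est = by / bx
    se = abs(se_y / bx)
    return {"estimate": est, "se": se, "beta_outcome": by, "beta_exposure": bx}
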