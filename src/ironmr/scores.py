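"""Weighted genotypic risk scores for iron biomarkers.

For each biomarker the score of individual *j* is

    raw_j = sum_i |w_i| * g_ij

over the SNPs with a published effect *w_i* on that biomarker, where
``g_ij`` is the risk-allele dosage.  Magnitude weights keep the stated score
semantics — the higher the score, the greater the genetic liability to LOW
iron status — even though the published effect estimates for iron, ferritin
and transferrin saturation are negative (risk alleles lower those
biomarkers).  Using |w| instead of w is a pure reflection of the score axis
and does not change any downstream inference.

Scores are reported per SD: ``standardized = (raw - mean) / SD`` over the
analysis sample (sample SD, ddof=1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, GenotypeError
from .genotypes import GenotypeMatrix
from .weights import SnpWeightTable, _check_biomarker

logger = logging.getLogger(__name__)

#: individuals missing more than this fraction of a score's SNPs are dropped
MAX_MISSING_FRACTION = 0.2


@dataclass(frozen=True)
class RiskScore:
    """A weighted genotypic risk score for one biomarker."""

    individual_ids: list[str]
    raw: np.ndarray
    standardized: np.ndarray
    biomarker: str
    snps_used: list[str]

    def __len__(self) -> int:
        return len(self.individual_ids)


def build_risk_score(
    genotypes: GenotypeMatrix,
    table: SnpWeightTable,
    biomarker: str,
) -> RiskScore:
    """Construct the weighted genotypic risk score for ``biomarker``.

    Dosages are re-oriented to the biomarker's risk allele (``2 - d``) where
    the matrix's counted allele differs — relevant only for rs8177240, whose
    risk allele is T for iron but G for transferrin and transferrin
    saturation.  Missing dosages are mean-imputed per SNP; individuals
    missing more than 20% of the selected SNPs are dropped with a warning.

    Raises
    ------
    GenotypeError
        If a selected SNP is absent from the matrix.
    DegenerateInputError
        If the raw score has zero variance (standardisation undefined).
    """
    _check_biomarker(biomarker)
    snps = table.select_snps_for_biomarker(biomarker)
    missing_snps = [s for s in snps if s not in genotypes.snp_ids]
    if missing_snps:
        raise GenotypeError(f"SNP(s) required for {biomarker} score absent: {missing_snps}")

    effects = table.effects_for_biomarker(biomarker)
    weights = np.array([abs(effects[s]) for s in snps])

    sub = genotypes.subset_snps(snps)
    dose = sub.dosage.copy()

    # orient each column to this biomarker's risk allele
    for j, snp in enumerate(snps):
        counted = genotypes.counted_allele.get(snp, table[snp].primary_risk_allele)
        risk = table.risk_allele(snp, biomarker)
        if counted != risk:
            dose[:, j] = 2.0 - dose[:, j]

    miss = np.isnan(dose)
    frac_missing = miss.mean(axis=1)
    keep = frac_missing <= MAX_MISSING_FRACTION
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning(
            "dropping %d individual(s) missing >%d%% of %s-score SNPs",
            n_drop, int(MAX_MISSING_FRACTION * 100), biomarker,
        )
        dose = dose[keep]
        miss = miss[keep]
    ids = [i for i, k in zip(sub.individual_ids, keep) if k]

    if dose.size == 0:
        raise DegenerateInputError("no individuals left after missingness filter")

    if miss.any():
        col_means = np.nanmean(dose, axis=0)
        # a column that is entirely missing has no defined mean
        if np.isnan(col_means).any():
            bad = [snps[j] for j in np.flatnonzero(np.isnan(col_means))]
            raise GenotypeError(f"SNP(s) with no observed dosages: {bad}")
        dose = np.where(miss, col_means[None, :], dose)

    raw = dose @ weights
    sd = raw.std(ddof=1) if len(raw) > 1 else 0.0
    if sd == 0.0:
        raise DegenerateInputError(
            f"{biomarker} raw score has zero variance; cannot standardise"
        )
    standardized = (raw - raw.mean()) / sd
    return RiskScore(
        individual_ids=ids,
        raw=raw,
        standardized=standardized,
        biomarker=biomarker,
        snps_used=snps,
    )


def orient_to_biomarker(
    genotypes: GenotypeMatrix,
    table: SnpWeightTable,
    biomarker: str,
) -> GenotypeMatrix:
    """Subset to the biomarker's SNPs with dosages counting its risk allele.

    Needed for per-allele association analyses, where each SNP's dosage
    must count the risk allele of the biomarker under analysis.
    """
    _check_biomarker(biomarker)
    snps = table.select_snps_for_biomarker(biomarker)
    sub = genotypes.subset_snps(snps)
    dose = sub.dosage
    counted: dict[str, str] = {}
    for j, snp in enumerate(snps):
        current = genotypes.counted_allele.get(snp, table[snp].primary_risk_allele)
        risk = table.risk_allele(snp, biomarker)
        if current != risk:
            dose[:, j] = 2.0 - dose[:, j]
        counted[snp] = risk
    sub.counted_allele = counted
    sub.orientation_biomarker = biomarker
    return sub


def all_scores(genotypes: GenotypeMatrix, table: SnpWeightTable) -> dict[str, RiskScore]:
    """Scores for every biomarker, keyed by biomarker label."""
    from .weights import BIOMARKERS

    return {bm: build_risk_score(genotypes, table, bm) for bm in BIOMARKERS}
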