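"""SNP weight table for iron-biomarker genotypic risk scores.

The package ships the 12-SNP weight table from the Genetics of Iron Status
(GIS) consortium genome-wide meta-analysis: per-SNP standardised effect
estimates on four iron biomarkers (serum iron, ferritin, transferrin,
transferrin saturation), together with the risk allele for each biomarker
(the allele associated with lower iron status — or higher transferrin, which
marks iron deficiency).  One locus, rs8177240 (*TF*), has discordant risk
alleles: T for serum iron, G for transferrin and transferrin saturation.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

from .exceptions import WeightTableParseError, WeightTableSchemaError

#: Canonical biomarker labels, in weight-table column order.
BIOMARKERS: tuple[str, ...] = ("iron", "ferritin", "transferrin", "transferrin_saturation")

# Column-header suffix <-> biomarker label.
_COLUMN_BIOMARKER = {
    "iron": "iron",
    "ferritin": "ferritin",
    "transferrin": "transferrin",
    "tsat": "transferrin_saturation",
}

_EXPECTED_COLUMNS = (
    ["snp_id", "gene"]
    + [f"risk_allele_{c}" for c in _COLUMN_BIOMARKER]
    + [f"beta_{c}" for c in _COLUMN_BIOMARKER]
    + ["genotyped"]
)

_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpWeight:
    """One SNP's risk-allele orientations and biomarker effect estimates.

    ``effect_by_biomarker`` holds the published effect (SD of biomarker per
    risk allele) for each biomarker the SNP reached genome-wide significance
    for; biomarkers without an estimate are simply absent from the map.
    """

    snp_id: str
    nearest_gene: str
    risk_allele_by_biomarker: dict[str, str]
    effect_by_biomarker: dict[str, float]
    genotyped: bool

    def __post_init__(self) -> None:
        if not self.effect_by_biomarker:
            raise WeightTableSchemaError(f"{self.snp_id}: all biomarker effects absent")
        for bm, beta in self.effect_by_biomarker.items():
            if bm not in BIOMARKERS:
                raise WeightTableSchemaError(f"{self.snp_id}: unknown biomarker {bm!r}")
            if not math.isfinite(beta) or beta == 0.0:
                raise WeightTableSchemaError(f"{self.snp_id}: non-finite or zero effect for {bm}")
            if bm not in self.risk_allele_by_biomarker:
                raise WeightTableSchemaError(f"{self.snp_id}: effect without risk allele for {bm}")

    @property
    def primary_risk_allele(self) -> str:
        """Risk allele of the first biomarker (table order) with an effect.

        Used as the stored counting allele for dosage matrices; scoring
        flips to the per-biomarker allele where it differs (rs8177240).
        """
        for bm in BIOMARKERS:
            if bm in self.effect_by_biomarker:
                return self.risk_allele_by_biomarker[bm]
        raise AssertionError("unreachable: record has >= 1 effect")


@dataclass(frozen=True)
class SnpWeightTable:
    """Ordered collection of :class:`SnpWeight` records."""

    records: tuple[SnpWeight, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise WeightTableSchemaError(f"duplicate rsIDs in weight table: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpWeight]:
        return iter(self.records)

    def __getitem__(self, snp_id: str) -> SnpWeight:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def select_snps_for_biomarker(self, biomarker: str) -> list[str]:
        """rsIDs with a non-absent effect for ``biomarker``, in table order."""
        _check_biomarker(biomarker)
        return [r.snp_id for r in self.records if biomarker in r.effect_by_biomarker]

    def effects_for_biomarker(self, biomarker: str) -> dict[str, float]:
        """Map rsID -> published effect estimate for ``biomarker``."""
        _check_biomarker(biomarker)
        return {
            r.snp_id: r.effect_by_biomarker[biomarker]
            for r in self.records
            if biomarker in r.effect_by_biomarker
        }

    def risk_allele(self, snp_id: str, biomarker: str) -> str:
        _check_biomarker(biomarker)
        rec = self[snp_id]
        try:
            return rec.risk_allele_by_biomarker[biomarker]
        except KeyError:
            raise WeightTableSchemaError(f"{snp_id} has no risk allele for {biomarker}") from None


def _check_biomarker(biomarker: str) -> None:
    if biomarker not in BIOMARKERS:
        raise WeightTableSchemaError(
            f"unknown biomarker {biomarker!r}; expected one of {BIOMARKERS}"
        )


def load_weight_table(path: str | Path) -> SnpWeightTable:
    """Load and validate a SNP weight table from TSV.

    Expected columns: ``snp_id``, ``gene``, one ``risk_allele_*`` and one
    ``beta_*`` column per biomarker (suffixes iron/ferritin/transferrin/tsat),
    and ``genotyped`` (0/1).  Blank cells mean the estimate is absent.

    Raises
    ------
    WeightTableSchemaError
        On unknown/missing columns, duplicate rsIDs, records with all
        effects absent, or non-finite effects.
    WeightTableParseError
        On malformed rows, naming the offending line.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise WeightTableParseError(f"{path}: empty file")
        unknown = set(reader.fieldnames) - set(_EXPECTED_COLUMNS)
        missing = set(_EXPECTED_COLUMNS) - set(reader.fieldnames)
        if unknown:
            raise WeightTableSchemaError(f"{path}: unknown column(s) {sorted(unknown)}")
        if missing:
            raise WeightTableSchemaError(f"{path}: missing column(s) {sorted(missing)}")

        records: list[SnpWeight] = []
        for lineno, row in enumerate(reader, start=2):
            if any(v is None for v in row.values()):
                raise WeightTableParseError(f"{path}:{lineno}: wrong number of fields")
            try:
                records.append(_parse_row(row))
            except WeightTableSchemaError:
                raise
            except (ValueError, KeyError) as exc:
                raise WeightTableParseError(f"{path}:{lineno}: {exc}") from exc
    return SnpWeightTable(tuple(records))


def _parse_row(row: dict[str, str]) -> SnpWeight:
    snp_id = row["snp_id"].strip()
    if not snp_id:
        raise ValueError("blank snp_id")
    alleles: dict[str, str] = {}
    effects: dict[str, float] = {}
    for col, bm in _COLUMN_BIOMARKER.items():
        allele = row[f"risk_allele_{col}"].strip()
        beta = row[f"beta_{col}"].strip()
        if allele:
            if allele not in _VALID_ALLELES:
                raise ValueError(f"invalid allele {allele!r} for {bm}")
            alleles[bm] = allele
        if beta:
            effects[bm] = float(beta)
    geno = row["genotyped"].strip()
    if geno not in {"0", "1"}:
        raise ValueError(f"genotyped flag must be 0/1, got {geno!r}")
    return SnpWeight(
        snp_id=snp_id,
        nearest_gene=row["gene"].strip(),
        risk_allele_by_biomarker=alleles,
        effect_by_biomarker=effects,
        genotyped=bool(int(geno)),
    )


def bundled_weight_table() -> SnpWeightTable:
    """The packaged 12-SNP GIS-consortium weight table."""
    with resources.as_file(
        resources.files("ironmr.data").joinpath("iron_snp_weights.tsv")
    ) as p:
        return load_weight_table(p)
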