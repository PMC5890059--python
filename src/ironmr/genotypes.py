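"""Risk-allele dosage matrices."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import GenotypeError


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of risk-allele dosages in [0, 2].

    ``dosage[i, j]`` is the (possibly fractional, for imputed data) count of
    the counted allele of SNP ``snp_ids[j]`` carried by ``individual_ids[i]``;
    NaN marks a missing call.  ``counted_allele`` records which allele each
    dosage counts, so scores for biomarkers with a different risk allele
    (rs8177240: T for iron, G for transferrin/saturation) can flip to
    ``2 - dosage`` on the fly.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    counted_allele: dict[str, str] = field(default_factory=dict)
    orientation_biomarker: str | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = len(self.individual_ids), len(self.snp_ids)
        if self.dosage.shape != (n, m):
            raise GenotypeError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{n} individuals x {m} SNPs"
            )
        if len(set(self.snp_ids)) != m:
            raise GenotypeError("snp_ids are not unique")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            raise GenotypeError("dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        try:
            j = self.snp_ids.index(snp_id)
        except ValueError:
            raise GenotypeError(f"SNP {snp_id} not in matrix") from None
        return self.dosage[:, j]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        missing = [s for s in snp_ids if s not in self.snp_ids]
        if missing:
            raise GenotypeError(f"SNP(s) absent from matrix: {missing}")
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            snp_ids=list(snp_ids),
            dosage=self.dosage[:, idx].copy(),
            counted_allele={s: self.counted_allele[s] for s in snp_ids if s in self.counted_allele},
            orientation_biomarker=self.orientation_biomarker,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.individual_ids, columns=self.snp_ids)

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: rows = individuals, columns = rsIDs, '.' = missing."""
        df = self.to_frame()
        df.index.name = "individual_id"
        df.to_csv(path, sep="\t", na_rep=".")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        counted_allele: dict[str, str] | None = None,
        orientation_biomarker: str | None = None,
    ) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."])
        return cls(
            individual_ids=[str(i) for i in df.index],
            snp_ids=[str(c) for c in df.columns],
            dosage=df.to_numpy(dtype=float),
            counted_allele=dict(counted_allele or {}),
            orientation_biomarker=orientation_biomarker,
        )
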