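"""Exception hierarchy for ironmr."""


class IronMRError(Exception):
    """Base class for all ironmr errors."""


class WeightTableParseError(IronMRError):
    """A row of the SNP weight table could not be parsed."""


class WeightTableSchemaError(IronMRError):
    """The SNP weight table violates its schema (columns or invariants)."""


class GenotypeError(IronMRError):
    """Invalid genotype data (missing SNPs, allele mismatch, bad dosages)."""


class DegenerateInputError(IronMRError):
    """Input is degenerate for the requested operation (e.g. zero variance)."""


class ConfigError(IronMRError):
    """Invalid simulation or pipeline configuration."""


class CollinearityError(IronMRError):
    """Design matrix is rank deficient."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design matrix is rank deficient: column {column!r} is collinear")


class SeparationError(IronMRError):
    """Logistic model suffers complete or quasi-complete separation."""
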