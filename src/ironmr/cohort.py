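"""Synthetic mother–child cohort generator.

Emulates the causal structure of the study design as a directed acyclic
graph:

    maternal genotype -> latent maternal iron status (SD units)
    latent iron  -> haemoglobin (g/dL, the measurable proxy)
    latent iron  -> iron supplementation (deficient mothers are supplemented)
    supplementation -> restores part of the iron deficit (hence dilution of
                       genetic associations among supplemented women)
    iron (post-supplementation) -> offspring outcomes (causal path under test)
    U (unmeasured) -> supplementation and outcomes (the collider arms)

Mendelian transmission links maternal and child genotypes (expected
mother–child dosage correlation 1/2 at Hardy-Weinberg equilibrium).  All
randomness flows from a single seed, so a cohort is a pure function of its
configuration.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import ConfigError, GenotypeError
from .genotypes import GenotypeMatrix
from .scores import build_risk_score
from .weights import SnpWeightTable, bundled_weight_table

#: Approximate European risk-allele frequencies for the 12 loci.  The risk
#: allele can be the major allele (e.g. rs1800562: wild-type G), so values
#: above 0.5 are expected.
DEFAULT_RISK_ALLELE_FREQS: dict[str, float] = {
    "rs1799945": 0.85,
    "rs1800562": 0.93,
    "rs855791": 0.42,
    "rs8177240": 0.67,
    "rs7385804": 0.38,
    "rs744653": 0.85,
    "rs651007": 0.20,
    "rs411988": 0.55,
    "rs9990333": 0.46,
    "rs4921915": 0.78,
    "rs6486121": 0.64,
    "rs174577": 0.67,
}

PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]

OUTCOME_COLUMNS = ["asthma", "atopy", "fev1_sd", "fvc_sd", "fef2575_sd", "log_ige"]


@dataclass(frozen=True)
class OutcomeMix:
    """Baseline outcome distribution parameters.

    Prevalences are for 7–9-year-old UK children (doctor-diagnosed current
    asthma ~12%, skin-prick atopy ~20%); total IgE is log-normal with a
    geometric mean around 40 kU/L.
    """

    asthma_prevalence: float = 0.12
    atopy_prevalence: float = 0.20
    ige_log_mean: float = 3.7
    ige_log_sd: float = 1.3
    ige_iron_effect: float = 0.0

    def validate(self) -> None:
        for name in ("asthma_prevalence", "atopy_prevalence"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ConfigError(f"{name} must be in (0,1), got {p}")
        if self.ige_log_sd <= 0:
            raise ConfigError("ige_log_sd must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the generator; the seed fixes every random draw.

    Parameters
    ----------
    n_mothers
        Cohort size.
    mafs
        Risk-allele frequency per SNP (None = packaged defaults).
    biomarker_h2
        Proportion of latent-iron variance explained by the genotypic score.
    gamma_supp
        Log-odds of late supplementation per SD of *low* iron status — the
        parameter that opens the collider path when mothers are
        preferentially supplemented for deficiency.
    supp_base_rate, supp_early_base_rate
        Marginal supplementation probabilities (late / early pregnancy).
    causal_effect
        Effect of maternal iron (SD) on each continuous offspring outcome
        (SD); also used as the log-OR per iron SD for binary outcomes.
    confounder_effect_supp, confounder_effect_outcome
        Arms of the unmeasured standard-normal confounder U.
    hb_loading
        g/dL of haemoglobin per SD of iron status.
    supp_restore
        Fraction of a supplemented mother's iron *deficit* that
        supplementation restores (clinical indication: only deficits are
        treated).
    """

    n_mothers: int = 5000
    mafs: dict[str, float] | None = None
    biomarker_h2: float = 0.03
    gamma_supp: float = 1.0
    supp_base_rate: float = 0.42
    supp_early_base_rate: float = 0.15
    causal_effect: float = 0.0
    confounder_effect_supp: float = 1.0
    confounder_effect_outcome: float = 1.0
    hb_loading: float = 0.6
    hb_mean: float = 11.5
    hb_sd: float = 1.0
    supp_restore: float = 0.5
    outcome_mix: OutcomeMix = field(default_factory=OutcomeMix)
    seed: int = 0

    def validate(self) -> None:
        if self.n_mothers < 1:
            raise ConfigError("n_mothers must be >= 1")
        if not 0.0 <= self.biomarker_h2 < 1.0:
            raise ConfigError(f"biomarker_h2 must be in [0,1), got {self.biomarker_h2}")
        for name in ("supp_base_rate", "supp_early_base_rate"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ConfigError(f"{name} must be in (0,1), got {p}")
        if not 0.0 <= self.supp_restore <= 1.0:
            raise ConfigError("supp_restore must be in [0,1]")
        if self.hb_sd <= 0:
            raise ConfigError("hb_sd must be positive")
        if self.mafs is not None:
            for snp, p in self.mafs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"allele frequency for {snp} outside [0,1]")
        self.outcome_mix.validate()

    def resolved_mafs(self, snp_ids: list[str]) -> np.ndarray:
        table = self.mafs if self.mafs is not None else DEFAULT_RISK_ALLELE_FREQS
        try:
            return np.array([table[s] for s in snp_ids])
        except KeyError as exc:
            raise ConfigError(f"no allele frequency configured for SNP {exc.args[0]}") from exc

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """One realisation of the generator."""

    maternal_genotypes: GenotypeMatrix
    child_genotypes: GenotypeMatrix
    latent_iron: np.ndarray
    post_supp_iron: np.ndarray
    confounder: np.ndarray
    cohort: pd.DataFrame
    truth: CohortConfig
    outcome_sd_scale: dict[str, float] = field(default_factory=dict)

    def score(self, biomarker: str, table: SnpWeightTable | None = None, child: bool = False):
        table = table or bundled_weight_table()
        geno = self.child_genotypes if child else self.maternal_genotypes
        return build_risk_score(geno, table, biomarker)


def simulate_maternal_genotypes(
    n: int,
    mafs: np.ndarray | list[float],
    seed: int | np.random.Generator,
    snp_ids: list[str] | None = None,
    counted_allele: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Draw n individuals' dosages at independent loci under HWE.

    Genotypes AA/Aa/aa are drawn with probabilities ((1-p)^2, 2p(1-p), p^2),
    i.e. dosage ~ Binomial(2, p), independently across SNPs.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs < 0) | (mafs > 1)):
        raise ConfigError("allele frequencies must lie in [0,1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dosage = rng.binomial(2, mafs[None, :], size=(n, len(mafs))).astype(float)
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(len(mafs))]
    return GenotypeMatrix(
        individual_ids=[f"M{i}" for i in range(n)],
        snp_ids=list(snp_ids),
        dosage=dosage,
        counted_allele=dict(counted_allele or {}),
    )


def simulate_child_genotypes(
    maternal: GenotypeMatrix,
    mafs: np.ndarray | list[float],
    seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Mendelian transmission: one maternal allele + one paternal allele.

    The maternal allele is drawn uniformly from the mother's two
    (Bernoulli(d/2) for dosage d); the paternal allele is Bernoulli(maf).
    Expected mother-child dosage correlation is 1/2 under HWE.
    """
    mafs = np.asarray(mafs, dtype=float)
    dose = maternal.dosage
    if np.isnan(dose).any() or not np.all(dose == np.round(dose)):
        raise GenotypeError("maternal dosages must be integer-valued for transmission")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    transmitted = rng.random(dose.shape) < dose / 2.0
    paternal = rng.random(dose.shape) < mafs[None, :]
    child = (transmitted.astype(float) + paternal.astype(float))
    return GenotypeMatrix(
        individual_ids=[f"C{i}" for i in range(maternal.n_individuals)],
        snp_ids=list(maternal.snp_ids),
        dosage=child,
        counted_allele=dict(maternal.counted_allele),
    )


def simulate_iron_and_proxy(
    genotypes: GenotypeMatrix,
    table: SnpWeightTable,
    config: CohortConfig,
    rng: np.random.Generator,
    confounder: np.ndarray,
) -> dict[str, np.ndarray]:
    """Latent iron status, supplementation, and the haemoglobin proxy.

    latent_iron = -sqrt(h2) * standardized iron score + sqrt(1-h2) * noise,
    so a higher score means lower iron.  Late supplementation follows
    logit P = logit(base) - gamma * iron + c_supp * U  (deficient mothers
    supplemented more).  Supplementation restores ``supp_restore`` of any
    deficit; late haemoglobin loads on post-supplementation iron, early
    haemoglobin on the unmodified latent iron.
    """
    config.validate()
    n = genotypes.n_individuals
    score = build_risk_score(genotypes, table, "iron").standardized
    h2 = config.biomarker_h2
    latent_iron = -np.sqrt(h2) * score + np.sqrt(1.0 - h2) * rng.standard_normal(n)

    lo_late = logit(config.supp_base_rate) - config.gamma_supp * latent_iron
    lo_late = lo_late + config.confounder_effect_supp * confounder
    supp_late = (rng.random(n) < expit(lo_late)).astype(int)

    lo_early = logit(config.supp_early_base_rate) - 0.5 * config.gamma_supp * latent_iron
    lo_early = lo_early + config.confounder_effect_supp * confounder
    supp_early = (rng.random(n) < expit(lo_early)).astype(int)

    deficit = np.maximum(0.0, -latent_iron)
    post_iron = latent_iron + config.supp_restore * deficit * supp_late

    hb_early = (
        config.hb_mean + 1.0  # haemodilution: early-pregnancy Hb runs ~1 g/dL higher
        + config.hb_loading * latent_iron
        + rng.normal(0.0, config.hb_sd, n)
    )
    hb_late = (
        config.hb_mean
        + config.hb_loading * post_iron
        + rng.normal(0.0, config.hb_sd, n)
    )
    return {
        "latent_iron": latent_iron,
        "post_supp_iron": post_iron,
        "hb_early": hb_early,
        "hb_late": hb_late,
        "supp_early": supp_early,
        "supp_late": supp_late,
    }


def simulate_offspring_outcomes(
    iron: np.ndarray,
    confounder: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Offspring respiratory/atopic outcomes given maternal iron exposure.

    Continuous lung-function outcomes are generated in SD units
    (causal_effect * iron + c_out * U + N(0,1), then re-standardised, which
    emulates the age/height/gender standardisation of real spirometry).
    Binary outcomes use a logistic model at the configured baseline
    prevalence; the 10 genomic principal components are independent noise
    covariates.
    """
    config.validate()
    n = len(iron)
    mix = config.outcome_mix
    cols: dict[str, np.ndarray] = {}
    scales: dict[str, float] = {}
    for name in ("fev1_sd", "fvc_sd", "fef2575_sd"):
        y = (
            config.causal_effect * iron
            + config.confounder_effect_outcome * confounder
            + rng.standard_normal(n)
        )
        sd = y.std(ddof=1)
        scales[name] = float(sd)
        cols[name] = (y - y.mean()) / sd
    for name, prev in (("asthma", mix.asthma_prevalence), ("atopy", mix.atopy_prevalence)):
        # low iron raises risk: log-odds decrease with iron status
        lo = logit(prev) - config.causal_effect * iron + config.confounder_effect_outcome * confounder
        cols[name] = (rng.random(n) < expit(lo)).astype(int)
    cols["log_ige"] = (
        mix.ige_log_mean
        + mix.ige_iron_effect * iron
        + rng.normal(0.0, mix.ige_log_sd, n)
    )
    for pc in PC_COLUMNS:
        cols[pc] = rng.standard_normal(n)
    df = pd.DataFrame(cols)
    # truth bookkeeping: SD divisor of each re-standardised outcome, so
    # parameter-recovery studies can map estimates back to model units
    df.attrs["outcome_sd_scale"] = scales
    return df


def generate_cohort(
    config: CohortConfig | None = None,
    table: SnpWeightTable | None = None,
) -> SyntheticCohort:
    """Run the full generative model; pure function of ``config``."""
    config = config or CohortConfig()
    config.validate()
    table = table or bundled_weight_table()
    rng = np.random.default_rng(config.seed)

    snp_ids = table.snp_ids
    mafs = config.resolved_mafs(snp_ids)
    counted = {r.snp_id: r.primary_risk_allele for r in table}

    maternal = simulate_maternal_genotypes(
        config.n_mothers, mafs, rng, snp_ids=snp_ids, counted_allele=counted
    )
    child = simulate_child_genotypes(maternal, mafs, rng)
    confounder = rng.standard_normal(config.n_mothers)

    iron = simulate_iron_and_proxy(maternal, table, config, rng, confounder)
    outcomes = simulate_offspring_outcomes(iron["post_supp_iron"], confounder, config, rng)

    cohort = pd.DataFrame(
        {
            "hb_early": iron["hb_early"],
            "hb_late": iron["hb_late"],
            "supp_early": iron["supp_early"],
            "supp_late": iron["supp_late"],
        }
    )
    cohort = pd.concat([cohort, outcomes], axis=1)
    cohort.index = pd.Index(maternal.individual_ids, name="individual_id")

    return SyntheticCohort(
        maternal_genotypes=maternal,
        child_genotypes=child,
        latent_iron=iron["latent_iron"],
        post_supp_iron=iron["post_supp_iron"],
        confounder=confounder,
        cohort=cohort,
        truth=config,
        outcome_sd_scale=dict(outcomes.attrs.get("outcome_sd_scale", {})),
    )


def config_with(config: CohortConfig, **kwargs) -> CohortConfig:
    """Copy a config with fields replaced (frozen-dataclass convenience)."""
    return replace(config, **kwargs)
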