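import numpy as np
import pytest

from ironmr.cohort import CohortConfig, generate_cohort
from ironmr.genotypes import GenotypeMatrix
from ironmr.weights import bundled_weight_table


@pytest.fixture(scope="session")
def table():
    return bundled_weight_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with an active causal effect, shared across tests."""
    cfg = CohortConfig(n_mothers=2000, causal_effect=0.1, seed=42)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def uniform_genotypes(table):
    """Deterministic 4-individual matrix over all 12 SNPs (dosages 0..2)."""
    rng = np.random.default_rng(7)
    dosage = rng.integers(0, 3, size=(4, 12)).astype(float)
    return GenotypeMatrix(
        individual_ids=[f"I{i}" for i in range(4)],
        snp_ids=table.snp_ids,
        dosage=dosage,
    )
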