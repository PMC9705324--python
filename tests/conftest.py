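import numpy as np
import pandas as pd
import pytest

from sigscore import (
    ExpressionMatrix,
    GeneSet,
    SyntheticCohortConfig,
    generate_bulk_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-gene, 10 vs 10 cohort with a planted 10-gene signature."""
    config = SyntheticCohortConfig(
        n_controls=10, n_cases=10, n_genes=200, n_signature_genes=10, effect_size=1.5, seed=11
    )
    matrix, annotations, truth = generate_bulk_cohort(config)
    return matrix, annotations, truth


@pytest.fixture(scope="session")
def planted_set(small_cohort):
    _, _, truth = small_cohort
    return GeneSet("SIG", truth.signature_genes)


@pytest.fixture(scope="session")
def random_matrix():
    """A plain random expression matrix with no structure (treat as read-only)."""
    rng = np.random.default_rng(42)
    genes = [f"G{i:03d}" for i in range(20)]
    samples = [f"S{i:02d}" for i in range(30)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(5, 2, (20, 30)), index=genes, columns=samples)
    )
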