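import numpy as np
import pytest

from krassig import ExpressionMatrix, SimulationParams, simulate_multi_cohort


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, two per phenotype group, log2 scale."""
    rng = np.random.default_rng(0)
    values = 8.0 + rng.normal(0, 0.5, size=(3, 4))
    sample_ids = ["m1", "m2", "w1", "w2"]
    return ExpressionMatrix(
        gene_ids=["AREG", "DUSP6", "FOSL1"],
        sample_ids=sample_ids,
        values=values,
        phenotype={"m1": "KRAS_mut", "m2": "KRAS_mut", "w1": "KRAS_wt", "w2": "KRAS_wt"},
    )


@pytest.fixture(scope="session")
def default_simulation():
    """The default planted simulation shared by recovery tests."""
    params = SimulationParams()  # 2000 genes, 20 planted, log2fc 1.5, seed 7
    systems, cohorts, truth = simulate_multi_cohort(params)
    return params, systems, cohorts, truth


def two_group_matrix(values: np.ndarray, labels=("KRAS_mut", "KRAS_wt")) -> ExpressionMatrix:
    """Wrap a (genes x samples) array, first half of columns in the first group."""
    n_genes, n_samples = values.shape
    half = n_samples // 2
    sample_ids = [f"s{i}" for i in range(n_samples)]
    phenotype = {s: (labels[0] if i < half else labels[1]) for i, s in enumerate(sample_ids)}
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=sample_ids,
        values=values,
        phenotype=phenotype,
    )
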