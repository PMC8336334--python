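import numpy as np
import pandas as pd
import pytest

from istmescore.containers import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection
from istmescore.synthetic import SimulationParams, make_reference_sets, simulate_dataset


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.uniform(0.5, 10.0, size=(12, 8)),
        index=[f"g{i}" for i in range(12)],
        columns=[f"s{j}" for j in range(8)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def small_clinical():
    rng = np.random.default_rng(11)
    n = 8
    return ClinicalTable(
        pd.DataFrame(
            {
                "os_time": rng.exponential(10, n).round(3),
                "os_event": rng.integers(0, 2, n),
                "age": rng.normal(60, 8, n).round(1),
            },
            index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def mini_cohort():
    """A small but structured cohort: fast enough for pipeline tests."""
    params = SimulationParams(
        n_genes=400, n_samples=80, n_immune_genes=30, n_stromal_genes=20,
        n_noise_factors=2, noise_module_size=25, seed=5,
    )
    expr, clin, gt = simulate_dataset(params)
    refs = make_reference_sets(gt, contamination=0.1, seed=5, all_genes=expr.gene_ids)
    return expr, clin, gt, refs
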