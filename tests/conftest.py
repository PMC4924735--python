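import numpy as np
import pandas as pd
import pytest

from mentx import ExpressionMatrix, SimulationConfig, generate_cohort
from mentx.io import LOG2


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort with fewer genes, for fast pipeline tests."""
    cfg = SimulationConfig(seed=7, n_genes=800, n_planted_up=60, n_planted_down=40)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One full default cohort (5000 genes, discovery-set structure)."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values: np.ndarray, genes=None, samples=None, scale=LOG2):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)
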