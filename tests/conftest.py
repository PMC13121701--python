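import numpy as np
import pandas as pd
import pytest

from medivar import SimConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A 500-gene study-like dataset with both factors active."""
    return generate(SimConfig(seed=11, n_genes=500))


@pytest.fixture(scope="session")
def null_dataset():
    """Noise-only dataset: no medium or donor effects anywhere."""
    return generate(SimConfig(seed=7, n_genes=400, sigma_medium=0.0, sigma_donor=0.0))


@pytest.fixture()
def random_matrix():
    """Unstructured positive intensity matrix, 50 genes x 12 samples."""
    rng = np.random.default_rng(123)
    vals = np.exp2(rng.normal(8, 2, size=(50, 12)))
    return pd.DataFrame(
        vals,
        index=[f"g{i:03d}" for i in range(50)],
        columns=[f"s{i:02d}" for i in range(12)],
    )
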