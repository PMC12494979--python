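import numpy as np
import pandas as pd
import pytest

from cytocycle import GeneratorConfig, simulate_population
from cytocycle.matrix import ExpressionMatrix
from cytocycle.preprocess import asinh_transform, percentile_normalize


@pytest.fixture(scope="session")
def default_dataset():
    """One default-noise population at the stimulated T-cell occupancy."""
    return simulate_population(GeneratorConfig(n_cells=20_000, seed=1))


@pytest.fixture(scope="session")
def normalized_default(default_dataset):
    """The default dataset taken through asinh + percentile normalization."""
    return percentile_normalize(asinh_transform(default_dataset.expression))


@pytest.fixture()
def matrix_factory():
    """Build a minimal ExpressionMatrix from an array at a given scale."""

    def _make(values, channels=None, scale_state="normalized", meta=None):
        values = np.asarray(values, dtype=float)
        if channels is None:
            channels = [f"m{i}" for i in range(values.shape[1])]
        if meta is None:
            meta = pd.DataFrame(index=range(values.shape[0]))
        return ExpressionMatrix(values, channels, meta, scale_state)

    return _make
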