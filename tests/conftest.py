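import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from rbabench import GenotypeDataset

SEED_BASE = 20250924


@pytest.fixture
def rng():
    return np.random.default_rng(SEED_BASE)


def make_dataset(X, y, predictive=(0,), config_id="test"):
    X = np.asarray(X, dtype=np.int8)
    return GenotypeDataset(
        genotypes=X,
        labels=np.asarray(y, dtype=np.int8),
        predictive_idx=tuple(predictive),
        feature_names=[f"F{i}" for i in range(X.shape[1])],
        config_id=config_id,
    )


@pytest.fixture
def toy_dataset():
    """8 instances x 3 features; feature 0 tracks the class, 2 is constant."""
    X = np.array(
        [
            [0, 1, 1],
            [0, 2, 1],
            [1, 0, 1],
            [0, 0, 1],
            [2, 1, 1],
            [2, 2, 1],
            [1, 0, 1],
            [2, 1, 1],
        ]
    )
    y = np.array([0, 0, 1, 0, 1, 1, 1, 0])
    return make_dataset(X, y, predictive=(0,))
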