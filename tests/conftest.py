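import numpy as np
import pytest

from mgmdhafs.data import FeatureTable
from mgmdhafs.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    """4 samples x 3 features covering all three kinds."""
    return FeatureTable(
        ["a", "b", "c", "d"],
        ["flag", "group", "score"],
        np.array([[0, 0, 1.5], [1, 1, -0.5], [0, 2, 0.3], [1, 1, 2.2]]),
        ["binary", "categorical", "continuous"],
    )


@pytest.fixture
def separable_dataset():
    """Two strongly informative Gaussian features, 1:5 imbalance, n=300."""
    cfg = SyntheticConfig(n_minority=50, n_majority=250,
                          continuous_effects=(3.0, 3.0), seed=1)
    return generate_dataset(cfg)


def make_labels(n_pos, n_neg):
    return np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
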