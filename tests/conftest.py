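import numpy as np
import pytest

from criafs.preprocess import DiscreteFeatureMatrix
from criafs.synthetic import SyntheticSpec, make_dataset


@pytest.fixture
def xor_triple():
    """Two uniform bits and their XOR: the canonical pure-synergy triple."""
    x = np.array([0, 0, 1, 1])
    y = np.array([0, 1, 0, 1])
    return x, y, x ^ y


@pytest.fixture
def small_matrix():
    """12-feature, 40-sample discrete fixture with mixed structure."""
    spec = SyntheticSpec(
        n_samples=40,
        n_main=3,
        n_redundant=3,
        n_interaction_pairs=1,
        n_noise=4,
        feature_noise_rate=0.1,
        seed=7,
    )
    matrix, _ = make_dataset(spec)
    assert matrix.n_features == 12
    return matrix


@pytest.fixture
def duplicate_feature_matrix():
    """Labels carry two independent bits; bit_a is duplicated exactly, so the
    informative-but-non-redundant bit_b should beat the duplicate."""
    rng = np.random.default_rng(11)
    n = 60
    bit_a = rng.integers(0, 2, n)
    bit_b = rng.integers(0, 2, n)
    labels = 2 * bit_a + bit_b
    noise = rng.integers(0, 2, n)
    values = np.column_stack([bit_a, bit_a.copy(), bit_b, noise])
    return DiscreteFeatureMatrix(values, ["bit_a", "dup", "bit_b", "noise"], labels)
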