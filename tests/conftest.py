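import numpy as np
import pytest

from grouprf import FeaturePartition, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """n=40, p=50, 5 groups, 2 relevant -- small but learnable."""
    X, y, truth = generate(SyntheticSpec(p=50, g=5, R=2, n=40, seed=7))
    return X, y, truth


@pytest.fixture
def separable_dataset():
    """Feature 1 separates the classes perfectly; all other features constant."""
    n = 10
    X = np.zeros((n, 4))
    y = np.array([0] * 5 + [1] * 5)
    X[:, 1] = np.where(y == 1, 2.0, -2.0)
    return X, y


@pytest.fixture
def three_group_partition():
    # features 0-1 -> A, 2-3 -> B, 4 -> C, 5 unassigned
    return FeaturePartition(["A", "B", "C"], [0, 0, 1, 1, 2, -1])
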