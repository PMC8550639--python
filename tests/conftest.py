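import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def Q2():
    """Asymmetric 2-state generator."""
    return np.array([[-1.0, 1.0], [2.0, -2.0]])


@pytest.fixture
def Q4():
    """The 4-state benchmark generator."""
    return np.array([
        [-3.00, 2.00, 1.00, 0.00],
        [1.00, -1.80, 0.75, 0.05],
        [0.15, 0.55, -1.05, 0.35],
        [0.00, 0.25, 0.40, -0.65],
    ])


def random_generator(K, rng, scale=1.0):
    """Random irreducible generator with Gamma off-diagonal rates."""
    Q = rng.gamma(1.5, scale, size=(K, K)) + 1e-3
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q
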