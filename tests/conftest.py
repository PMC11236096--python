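import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_stochastic(rng, n):
    """Random strictly positive row-stochastic matrix."""
    X = rng.random((n, n)) + 1e-3
    return X / X.sum(axis=1, keepdims=True)


def random_connected_weighted(rng, n):
    """Random complete positive symmetric weight matrix, zero diagonal."""
    W = rng.random((n, n)) + 0.1
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return W
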