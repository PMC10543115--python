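import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_weighted_graph(rng, n, density=0.6, connected=False):
    """Random symmetric nonnegative weight matrix for oracle comparisons."""
    while True:
        W = rng.random((n, n)) * 5
        W[rng.random((n, n)) > density] = 0.0
        W = np.triu(W, 1)
        W = W + W.T
        if not connected:
            return W
        from neonet.construct import is_connected

        if is_connected(W):
            return W


@pytest.fixture
def two_k3():
    """Two disconnected unit-weight triangles on 6 nodes."""
    W = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        W[a, b] = W[b, a] = 1.0
    return W
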