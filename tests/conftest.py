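import numpy as np
import pytest

from spanet.containers import DirectedNetwork


def net_from_rows(rows):
    a = np.array(rows, dtype=int)
    labels = [chr(ord("a") + i) for i in range(a.shape[0])]
    return DirectedNetwork(labels, a)


def random_digraph(n, p, seed):
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(a, 0)
    return DirectedNetwork([f"v{i}" for i in range(n)], a)


@pytest.fixture
def star5():
    """Undirected star on 5 nodes, center a."""
    a = np.zeros((5, 5), int)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return DirectedNetwork(list("abcde"), a)


@pytest.fixture
def chain3():
    """Directed chain a -> b -> c."""
    return net_from_rows([[0, 1, 0], [0, 0, 1], [0, 0, 0]])


@pytest.fixture
def cycle3():
    return net_from_rows([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
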