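import numpy as np
import pytest

from nnembed.netio import DirectedBinaryNetwork


@pytest.fixture
def cycle3():
    """Directed 3-cycle a->b->c->a."""
    return DirectedBinaryNetwork(
        np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]]), ["a", "b", "c"]
    )


@pytest.fixture
def path3():
    """Directed path a->b->c."""
    return DirectedBinaryNetwork(
        np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]]), ["a", "b", "c"]
    )


def random_digraph(n: int, density: float, seed: int) -> DirectedBinaryNetwork:
    """Random directed binary network with at least one edge, no self-loops."""
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(a, 0)
    if a.sum() == 0:
        i, j = rng.integers(n), rng.integers(n - 1)
        a[i, j + (j >= i)] = 1
    return DirectedBinaryNetwork(a)
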