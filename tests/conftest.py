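import numpy as np
import pytest

from spamscale.proximity import ItemSet, ProximityMatrix, ProximityStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_items():
    return ItemSet(("a", "b", "c", "d", "e"))


@pytest.fixture
def random_matrix(rng, small_items):
    """A valid random 5x5 proximity matrix."""
    n = small_items.n_items
    vals = np.abs(rng.normal(size=(n, n)))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return ProximityMatrix("s1", small_items, vals)


def line_stack(positions, items=None):
    """Single-subject stack whose dissimilarities are 1-D line distances."""
    positions = np.asarray(positions, float)
    n = len(positions)
    if items is None:
        items = ItemSet(tuple(chr(ord("a") + i) for i in range(n)))
    D = np.abs(positions[:, None] - positions[None, :])
    return ProximityStack(items, (ProximityMatrix("s1", items, D),))
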