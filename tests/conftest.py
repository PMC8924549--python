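import numpy as np
import pytest

from neuroskel.skeleton import Skeleton


@pytest.fixture
def straight_skeleton():
    """Unbranched 100 nm path along x with 11 nodes."""
    xyz = np.column_stack([np.linspace(0, 100, 11), np.zeros(11), np.zeros(11)])
    return Skeleton.from_arrays(xyz, np.ones(11), np.arange(-1, 10))


@pytest.fixture
def y_skeleton():
    """Root -> junction, then two symmetric daughters at 90 degrees."""
    xyz = np.array([[0, 0, 0], [10, 0, 0], [20, 10, 0], [20, -10, 0.0]])
    return Skeleton.from_arrays(xyz, np.ones(4), np.array([-1, 0, 1, 1]))


def random_skeleton(rng, n_nodes=20):
    """Random tree: node k's parent is uniform among earlier nodes."""
    xyz = rng.uniform(0, 1000, size=(n_nodes, 3))
    radius = rng.uniform(0.1, 50, size=n_nodes)
    parent = np.array([-1] + [int(rng.integers(k)) for k in range(1, n_nodes)])
    return Skeleton.from_arrays(xyz, radius, parent)
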