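import numpy as np
import pytest

from pollinet import InteractionNetwork, Partition


@pytest.fixture
def two_block_net():
    """4x4 matrix of ones in two 2x2 blocks; planted partition has Q = 0.5."""
    A = np.zeros((4, 4), dtype=np.int64)
    A[:2, :2] = 1
    A[2:, 2:] = 1
    return InteractionNetwork(
        A, ["p1", "p2", "p3", "p4"], ["k1", "k2", "k3", "k4"]
    )


@pytest.fixture
def two_block_partition():
    return Partition(
        plant_modules={"p1": 1, "p2": 1, "p3": 2, "p4": 2},
        pollinator_modules={"k1": 1, "k2": 1, "k3": 2, "k4": 2},
        q=0.5,
    )


@pytest.fixture
def tiny_net():
    """[[3,0],[0,1]]: two plants with disjoint pollinator faunas."""
    return InteractionNetwork(
        np.array([[3, 0], [0, 1]]), ["A", "B"], ["x", "y"]
    )


def random_network(rng, n_plants=5, n_polls=6, max_count=4):
    """A random valid network (no all-zero rows/columns)."""
    while True:
        A = rng.integers(0, max_count + 1, size=(n_plants, n_polls))
        if (A.sum(axis=1) > 0).all() and (A.sum(axis=0) > 0).all():
            return InteractionNetwork(
                A,
                [f"p{i}" for i in range(n_plants)],
                [f"k{j}" for j in range(n_polls)],
            )
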