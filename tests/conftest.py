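import numpy as np
import pytest

from simbins import MultiplexNetwork, layer_adjacency


@pytest.fixture
def triangle_plus_isolated():
    """Triangle 0-1-2 in the target layer, nodes 3..5 isolated there;
    auxiliary layer mixes target edges with an extra wedge at node 2."""
    return MultiplexNetwork(
        node_ids=(0, 1, 2, 3, 4, 5),
        layers={
            "target": {(0, 1), (1, 2), (0, 2)},
            "auxiliary": {(0, 1), (1, 2), (3, 4), (2, 5)},
        },
    )


@pytest.fixture
def path_graph():
    """Path a-b-c as a single-layer network."""
    return MultiplexNetwork(
        node_ids=("a", "b", "c"),
        layers={"L": {("a", "b"), ("b", "c")}},
    )


@pytest.fixture
def path_adjacency(path_graph):
    return layer_adjacency(path_graph, "L")


def random_connected_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random connected simple graph on n nodes: a random spanning tree
    plus each remaining pair independently with probability 0.3."""
    A = np.zeros((n, n))
    order = rng.permutation(n)
    for k in range(1, n):
        j = order[k]
        i = order[rng.integers(0, k)]
        A[i, j] = A[j, i] = 1.0
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] == 0 and rng.random() < 0.3:
                A[i, j] = A[j, i] = 1.0
    return A
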