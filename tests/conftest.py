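import numpy as np
import pytest

from msbrainnet import AdjacencyMatrix, ScenarioSpec


def graph_from_edges(n, edges, weights=None):
    """Adjacency matrix from an edge list on nodes 0..n-1."""
    w = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        val = 1.0 if weights is None else weights[k]
        w[i, j] = w[j, i] = val
    return AdjacencyMatrix(weights=w, node_labels=[f"n{i}" for i in range(n)])


def clique_union(sizes):
    """Disjoint union of complete graphs of the given sizes."""
    n = sum(sizes)
    w = np.zeros((n, n))
    start = 0
    blocks = []
    for s in sizes:
        w[start : start + s, start : start + s] = 1.0
        blocks.append(list(range(start, start + s)))
        start += s
    np.fill_diagonal(w, 0.0)
    adj = AdjacencyMatrix(weights=w, node_labels=[f"n{i}" for i in range(n)])
    return adj, blocks


@pytest.fixture(scope="session")
def default_spec():
    return ScenarioSpec(seed=11)


@pytest.fixture
def micro_spec():
    """Smallest internally consistent two-arm scenario (2 + 2 subjects)."""
    return ScenarioSpec(
        seed=3,
        arm_sizes={"DMF": 2, "NAT": 2},
        responder_split={"DMF_R": 1, "DMF_NR": 1, "NAT_active": 1},
        activity_breakdown={"DMF": (1, 1, 1), "NAT": (1, 0, 0)},
    )
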