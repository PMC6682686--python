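"""Modularity core: closed forms, oracle agreement, thresholding."""
import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msbrainnet import (
    AdjacencyMatrix,
    UndefinedModularityError,
    ValidationError,
    brute_force_partition,
    modularity_value,
    newman_spectral_partition,
    threshold_at_density,
)
from conftest import clique_union, graph_from_edges


class TestModularityValue:
    def test_single_module_is_zero_for_any_graph(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(3, 9)
            w = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
            w = np.triu(w, 1)
            w = w + w.T
            if w.sum() == 0:
                continue
            adj = AdjacencyMatrix(w, [f"n{i}" for i in range(n)])
            assert modularity_value(adj, np.zeros(n, dtype=int)) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_two_disconnected_triangles_split_by_component(self):
        adj, blocks = clique_union([3, 3])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert modularity_value(adj, labels) == pytest.approx(0.5, abs=1e-12)

    def test_k4_even_split_closed_form(self):
        adj, _ = clique_union([4])
        assert modularity_value(adj, np.array([0, 0, 1, 1])) == pytest.approx(
            -1 / 6, abs=1e-12
        )

    def test_empty_graph_rejected(self):
        adj = AdjacencyMatrix(np.zeros((3, 3)), ["a", "b", "c"])
        with pytest.raises(UndefinedModularityError):
            modularity_value(adj, np.zeros(3, dtype=int))

    def test_agrees_with_networkx_on_random_partitions(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            n = int(rng.integers(4, 10))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            w = nx.to_numpy_array(g)
            adj = AdjacencyMatrix(w, [f"n{i}" for i in range(n)])
            labels = rng.integers(0, 3, n)
            comms = [set(np.where(labels == c)[0]) for c in np.unique(labels)]
            expected = nx.community.modularity(g, comms)
            assert modularity_value(adj, labels) == pytest.approx(expected, abs=1e-12)


class TestSpectralPartition:
    def test_complete_graph_is_indivisible(self):
        adj, _ = clique_union([6])
        part = newman_spectral_partition(adj)
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_cliques_recovered(self):
        adj, blocks = clique_union([4, 4])
        part = newman_spectral_partition(adj)
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5, abs=1e-12)
        labels = part.labels_for(adj.node_labels)
        for block in blocks:
            assert len(set(labels[block])) == 1

    def test_ring_of_four_5cliques_gives_four_modules(self):
        # four 5-cliques, consecutive cliques joined by a single edge
        n = 20
        w = np.zeros((n, n))
        for b in range(4):
            idx = range(5 * b, 5 * b + 5)
            for i, j in itertools.combinations(idx, 2):
                w[i, j] = w[j, i] = 1.0
        for b in range(4):
            i, j = 5 * b + 4, (5 * b + 5) % n
            w[i, j] = w[j, i] = 1.0
        adj = AdjacencyMatrix(w, [f"n{i}" for i in range(n)])
        part = newman_spectral_partition(adj)
        assert part.n_modules == 4
        labels = part.labels_for(adj.node_labels)
        for b in range(4):
            assert len(set(labels[5 * b : 5 * b + 5])) == 1

    def test_q_self_consistency(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(5, 12))
            w = (rng.random((n, n)) < 0.4).astype(float)
            w = np.triu(w, 1)
            w = w + w.T
            if w.sum() == 0:
                continue
            adj = AdjacencyMatrix(w, [f"n{i}" for i in range(n)])
            part = newman_spectral_partition(adj)
            assert part.q == pytest.approx(
                modularity_value(adj, part), abs=1e-12
            )
            assert part.q >= -1e-12  # splits only accepted on positive gain

    def test_matches_brute_force_on_small_connected_graphs(self):
        """Heuristic-quality bound: spectral Q >= 0.95 * optimal Q (<=8 nodes)."""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 25:
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g):
                continue
            adj = AdjacencyMatrix(nx.to_numpy_array(g), [f"n{i}" for i in range(n)])
            spectral = newman_spectral_partition(adj)
            optimal = brute_force_partition(adj)
            assert spectral.q <= optimal.q + 1e-12
            if optimal.q > 0:
                assert spectral.q >= 0.95 * optimal.q
            checked += 1

    def test_equals_brute_force_on_clique_families(self):
        for sizes in ([4], [6], [3, 3], [4, 4], [3, 4], [3, 3, 3]):
            adj, _ = clique_union(sizes)
            assert newman_spectral_partition(adj).q == pytest.approx(
                brute_force_partition(adj).q, abs=1e-12
            )

    def test_weighted_scale_invariance(self):
        rng = np.random.default_rng(4)
        w = rng.random((8, 8)) * (rng.random((8, 8)) < 0.5)
        w = np.triu(w, 1)
        w = w + w.T
        adj1 = AdjacencyMatrix(w, [f"n{i}" for i in range(8)])
        adj2 = AdjacencyMatrix(w * 7.3, [f"n{i}" for i in range(8)])
        p1 = newman_spectral_partition(adj1)
        p2 = newman_spectral_partition(adj2)
        assert p1.assignment == p2.assignment
        assert p1.q == pytest.approx(p2.q, abs=1e-12)

    def test_agrees_with_igraph_leading_eigenvector_on_planted_blocks(self):
        """Independent implementation of the same algorithm as cross-check."""
        igraph = pytest.importorskip("igraph")
        adj, blocks = clique_union([6, 6, 6])
        part = newman_spectral_partition(adj)
        g = igraph.Graph.Adjacency(
            (adj.weights > 0).tolist(), mode="undirected"
        )
        ref = g.community_leading_eigenvector()
        assert part.n_modules == len(ref)
        assert part.q == pytest.approx(ref.modularity, abs=1e-9)


class TestBruteForce:
    @pytest.mark.parametrize(
        "edges, n, expected_modules, expected_q",
        [
            ([(0, 1)], 2, 1, 0.0),  # any split of one edge has Q = -0.5
            ([(0, 1), (1, 2), (0, 2)], 3, 1, 0.0),  # triangle indivisible
            ([(0, 1), (2, 3)], 4, 2, 0.5),  # two disconnected edges
        ],
    )
    def test_enumeration_examples(self, edges, n, expected_modules, expected_q):
        part = brute_force_partition(graph_from_edges(n, edges))
        assert part.n_modules == expected_modules
        assert part.q == pytest.approx(expected_q, abs=1e-12)

    def test_refuses_large_graphs(self):
        adj, _ = clique_union([11])
        with pytest.raises(ValidationError, match="max_nodes"):
            brute_force_partition(adj)


class TestThresholdAtDensity:
    def test_exact_edge_counts_at_68_nodes(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(68, 68))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        for d, expected in [(0.10, 227), (0.50, 1139)]:
            adj = threshold_at_density(m, d)
            assert int(adj.weights.sum() / 2) == expected

    def test_keeps_the_strongest_signed_entries(self):
        m = np.array(
            [
                [0.0, 0.9, -0.8, 0.1],
                [0.9, 0.0, 0.5, -0.2],
                [-0.8, 0.5, 0.0, 0.3],
                [0.1, -0.2, 0.3, 0.0],
            ]
        )
        adj = threshold_at_density(m, 0.5)  # keep floor(0.5*6) = 3 edges
        kept = {(i, j) for i in range(4) for j in range(i + 1, 4) if adj.weights[i, j]}
        assert kept == {(0, 1), (1, 2), (2, 3)}  # 0.9, 0.5, 0.3; -0.8 excluded

    def test_absolute_ranking_flag_includes_negative_edges(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = -0.9
        m[2, 3] = m[3, 2] = 0.5
        adj = threshold_at_density(m, 1 / 6, rank_by="absolute")
        assert adj.weights[0, 1] == 1.0

    def test_idempotent_at_same_density(self):
        rng = np.random.default_rng(6)
        m = rng.normal(size=(20, 20))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        once = threshold_at_density(m, 0.2)
        twice = threshold_at_density(once.weights, 0.2)
        assert np.array_equal(once.weights, twice.weights)

    def test_deterministic_tie_break(self):
        m = np.ones((5, 5)) - np.eye(5)  # all entries tied
        adj = threshold_at_density(m, 0.3)  # keep floor(0.3*10) = 3 edges
        kept = [(i, j) for i in range(5) for j in range(i + 1, 5) if adj.weights[i, j]]
        assert kept == [(0, 1), (0, 2), (0, 3)]  # lexicographic (row, col)

    @pytest.mark.parametrize("d", [0.0, -0.1, 1.5])
    def test_rejects_bad_density(self, d):
        with pytest.raises(ValidationError):
            threshold_at_density(np.zeros((4, 4)), d)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_spectral_never_beats_brute_force_property(seed):
    """On random graphs <= 7 nodes, spectral Q is bounded by the global optimum."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))
    w = (rng.random((n, n)) < 0.5).astype(float)
    w = np.triu(w, 1)
    w = w + w.T
    if w.sum() == 0:
        return
    adj = AdjacencyMatrix(w, [f"n{i}" for i in range(n)])
    assert newman_spectral_partition(adj).q <= brute_force_partition(adj).q + 1e-12
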