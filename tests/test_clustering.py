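"""Thresholding, clique synchronization (with brute-force certificate), Louvain."""

import itertools

import numpy as np
import pytest

from symrep.clustering import (
    FunctionalNetwork,
    clique_synchronization,
    louvain_partition,
    modularity,
    threshold_matrix,
)
from symrep.partition import Partition
from symrep.synchrony import AveragedMatrix, MetricSpec


def _avg(labels, weights):
    n = len(labels)
    V = np.full((n, n), np.nan)
    np.fill_diagonal(V, 1.0)
    C = np.zeros((n, n), int)
    np.fill_diagonal(C, 1)
    for (u, v), w in weights.items():
        i, j = labels.index(u), labels.index(v)
        V[i, j] = V[j, i] = w
        C[i, j] = C[j, i] = 1
    return AveragedMatrix(MetricSpec("pearson"), tuple(labels), V, C)


def _net(labels, weights):
    edges = {(min(u, v), max(u, v)): w for (u, v), w in weights.items()}
    return FunctionalNetwork(tuple(labels), edges, MetricSpec("pearson"))


def _certify_clique(net, clique):
    """Independent re-check of the clique acceptance inequality."""
    nn = len(clique)
    if nn == 1:
        return True
    internal = sum(net.weight(u, v) for u, v in itertools.combinations(clique, 2))
    for k in clique:
        for k2 in net.neighbors(k):
            if k2 in clique:
                continue
            if internal < nn * (nn - 1) / 2 * net.weight(k, k2):
                return False
    return True


class TestThreshold:
    def test_min_of_row_maxima_rule(self):
        avg = _avg(["1", "2", "3"], {("1", "2"): 0.9, ("1", "3"): 0.4, ("2", "3"): 0.7})
        net = threshold_matrix(avg)
        assert set(net.edges) == {("1", "2"), ("2", "3")}

    def test_equal_weights_keep_complete_graph(self):
        avg = _avg(list("abcd"), {(u, v): 0.5 for u, v in itertools.combinations("abcd", 2)})
        net = threshold_matrix(avg)
        assert len(net.edges) == 6

    def test_every_neuron_keeps_an_edge(self, rng):
        labels = [f"n{i}" for i in range(8)]
        weights = {
            (u, v): float(rng.random())
            for u, v in itertools.combinations(labels, 2)
        }
        net = threshold_matrix(_avg(labels, weights))
        for x in labels:
            assert net.neighbors(x), x

    def test_single_defined_pair(self):
        avg = _avg(["a", "b"], {("a", "b"): 0.3})
        net = threshold_matrix(avg)
        assert set(net.edges) == {("a", "b")}

    def test_percolation_stops_at_one_component(self):
        avg = _avg(
            list("abcd"),
            {("a", "b"): 0.9, ("c", "d"): 0.8, ("b", "c"): 0.7, ("a", "c"): 0.6,
             ("a", "d"): 0.5, ("b", "d"): 0.4},
        )
        net = threshold_matrix(avg, rule="percolation")
        assert set(net.edges) == {("a", "b"), ("c", "d"), ("b", "c")}
        assert net.n_components == 1

    def test_all_undefined_rejected(self):
        V = np.full((2, 2), np.nan)
        np.fill_diagonal(V, 1.0)
        avg = AveragedMatrix(MetricSpec("pearson"), ("a", "b"), V, np.eye(2, dtype=int))
        with pytest.raises(ValueError):
            threshold_matrix(avg)


class TestCliqueSynchronization:
    def test_strong_triangle_with_weak_external_edge(self):
        net = _net(
            "abcd",
            {("a", "b"): 0.9, ("a", "c"): 0.9, ("b", "c"): 0.9, ("a", "d"): 0.2},
        )
        p = clique_synchronization(net)
        assert frozenset("abc") in p.clusters
        assert frozenset("d") in p.clusters

    def test_strong_external_edge_rejects_triangle(self):
        net = _net(
            "abcd",
            {("a", "b"): 0.5, ("a", "c"): 0.5, ("b", "c"): 0.5, ("a", "d"): 1.0},
        )
        p = clique_synchronization(net)
        assert frozenset("abc") not in p.clusters
        # the pair (a, d) dominates: internal 1.0 >= any outside edge
        assert frozenset("ad") in p.clusters

    def test_isolated_node_is_singleton(self):
        net = _net("abc", {("a", "b"): 0.5})
        p = clique_synchronization(net)
        assert frozenset("c") in p.clusters

    def test_emitted_cliques_pass_independent_certificate(self, rng):
        for trial in range(20):
            labels = [f"n{i}" for i in range(7)]
            weights = {
                (u, v): float(rng.random())
                for u, v in itertools.combinations(labels, 2)
                if rng.random() < 0.6
            }
            if not weights:
                continue
            net = _net(labels, weights)
            p = clique_synchronization(net)
            assert p.labels == frozenset(labels)
            for cluster in p.clusters:
                if len(cluster) > 1:
                    assert _certify_clique(net, cluster)


class TestLouvain:
    def _two_triangles(self):
        w = {}
        for tri in ("abc", "def"):
            for u, v in itertools.combinations(tri, 2):
                w[(u, v)] = 1.0
        return _net("abcdef", w)

    def test_two_triangles_q_half(self):
        net = self._two_triangles()
        p = louvain_partition(net, n_runs=20, seed=0)
        assert p.same_partition(Partition.from_sets([set("abc"), set("def")]))
        assert modularity(net, p) == pytest.approx(0.5)

    def test_exhaustive_modularity_maximum(self):
        # best partition over all set-partitions of 6 nodes
        net = self._two_triangles()

        def all_partitions(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for sub in all_partitions(rest):
                for i in range(len(sub)):
                    yield sub[:i] + [sub[i] | {first}] + sub[i + 1:]
                yield sub + [{first}]

        best = max(
            (Partition.from_sets(s) for s in all_partitions(list("abcdef"))),
            key=lambda p: modularity(net, p),
        )
        assert modularity(net, best) == pytest.approx(0.5)
        assert best.same_partition(louvain_partition(net, 20, 0))

    def test_single_triangle_q_zero(self):
        net = _net("abc", {("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0})
        p = louvain_partition(net, n_runs=5, seed=1)
        assert p.n_clusters == 1
        assert modularity(net, p) == pytest.approx(0.0)

    def test_determinism(self):
        net = self._two_triangles()
        a = louvain_partition(net, 10, seed=42)
        b = louvain_partition(net, 10, seed=42)
        assert a.same_partition(b)

    def test_reported_q_matches_networkx(self, rng):
        import networkx as nx

        labels = [f"n{i}" for i in range(8)]
        weights = {
            (u, v): float(rng.random())
            for u, v in itertools.combinations(labels, 2)
            if rng.random() < 0.5
        }
        net = _net(labels, weights)
        p = louvain_partition(net, 10, 0)
        q_ours = modularity(net, p)
        q_nx = nx.community.modularity(net.to_networkx(), [set(c) for c in p.clusters],
                                       weight="weight")
        assert q_ours == pytest.approx(q_nx, abs=1e-12)
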