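"""Functional-network construction and synchrony-cluster extraction.

An averaged synchrony matrix is thresholded into an undirected weighted
functional network, from which candidate clusters of synchrony are
extracted by two methods:

* clique synchronization — a fully connected clique of N nodes is
  accepted when its internal weight sum is at least N(N-1)/2 times every
  edge from a clique member to an outside neighbour;
* Louvain community detection — the heuristic is restarted many times and
  the partition with the highest (directly re-evaluated) modularity Q is
  kept.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .partition import Partition, dedup_partitions
from .synchrony import AveragedMatrix, MetricSpec

__all__ = [
    "FunctionalNetwork",
    "threshold_matrix",
    "clique_synchronization",
    "louvain_partition",
    "modularity",
    "dedup_partitions",
]


@dataclass
class FunctionalNetwork:
    """Undirected weighted graph of surviving synchrony entries."""

    labels: tuple[str, ...]
    edges: dict[tuple[str, str], float]  # keys sorted pairs (u < v)
    source_metric: MetricSpec
    threshold_rule: str = "global-min-max"

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        for (u, v) in self.edges:
            if u >= v:
                raise ValueError(f"edge key must be a sorted pair, got {(u, v)}")

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    def neighbors(self, x: str) -> list[str]:
        return [v if u == x else u for (u, v) in self.edges if x in (u, v)]

    def weight(self, u: str, v: str) -> float:
        return self.edges[(min(u, v), max(u, v))]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g


def threshold_matrix(avg: AveragedMatrix, rule: str = "global-min-max") -> FunctionalNetwork:
    """Threshold an averaged matrix into a functional network.

    ``rule="global-min-max"`` (default): with M_k the largest defined
    off-diagonal entry of neuron k, the threshold is tau = min_k M_k and
    every entry >= tau becomes an edge. Every neuron keeps at least its
    strongest link, parameter-free.

    ``rule="percolation"``: edges are added in decreasing weight (ties in
    lexicographic label order) until the graph forms a single connected
    component.
    """
    n = len(avg.labels)
    if n < 2:
        raise ValueError("need at least two labels")
    V = avg.values.copy().astype(float)
    np.fill_diagonal(V, np.nan)
    defined = np.isfinite(V)
    if not defined.any():
        raise ValueError("all off-diagonal entries are undefined")
    pairs = [
        (avg.labels[i], avg.labels[j], float(V[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if defined[i, j]
    ]
    if rule == "global-min-max":
        row_max = np.where(defined.any(axis=1), np.nanmax(np.where(defined, V, -np.inf), axis=1), np.nan)
        tau = np.nanmin(row_max)
        edges = {(u, v): w for (u, v, w) in pairs if w >= tau}
    elif rule == "percolation":
        order = sorted(pairs, key=lambda t: (-t[2], t[0], t[1]))
        g = nx.Graph()
        g.add_nodes_from(avg.labels)
        edges = {}
        for (u, v, w) in order:
            edges[(u, v)] = w
            g.add_edge(u, v)
            if nx.number_connected_components(g) == 1:
                break
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    return FunctionalNetwork(avg.labels, edges, avg.metric, rule)


def _clique_ok(net: FunctionalNetwork, clique: tuple[str, ...]) -> bool:
    """Acceptance test: internal weight sum >= (N(N-1)/2) * every outside edge."""
    nn = len(clique)
    members = set(clique)
    internal = sum(net.weight(u, v) for u, v in itertools.combinations(clique, 2))
    bound = nn * (nn - 1) / 2.0
    for k in clique:
        for k2 in net.neighbors(k):
            if k2 in members:
                continue
            if internal < bound * net.weight(k, k2):
                return False
    return True


def _internal_weight(net: FunctionalNetwork, clique: tuple[str, ...]) -> float:
    return sum(net.weight(u, v) for u, v in itertools.combinations(clique, 2))


def clique_synchronization(net: FunctionalNetwork, max_cliques: int = 200_000) -> Partition:
    """Greedy partition of the network into accepted synchronous cliques.

    Candidate cliques are swept in decreasing size, then decreasing
    internal weight sum; an accepted clique removes its nodes from
    further consideration, and leftover nodes become singletons. The
    acceptance test always uses outside neighbourhoods of the full
    network. When full clique enumeration would exceed ``max_cliques``,
    candidates fall back to maximal cliques iteratively shrunk by
    dropping their weakest member.
    """
    if not net.labels:
        raise ValueError("empty network")
    g = net.to_networkx()
    candidates: list[tuple[str, ...]] = []
    count = 0
    exhaustive = True
    for cl in nx.enumerate_all_cliques(g):
        if len(cl) >= 2:
            candidates.append(tuple(sorted(cl)))
        count += 1
        if count > max_cliques:
            exhaustive = False
            break
    if not exhaustive:
        candidates = []
        for cl in nx.find_cliques(g):
            cl = tuple(sorted(cl))
            while len(cl) >= 2:
                candidates.append(cl)
                # shrink by dropping the member with least internal weight
                drop = min(cl, key=lambda x: sum(net.weight(x, y) for y in cl if y != x))
                cl = tuple(y for y in cl if y != drop)
        candidates = sorted(set(candidates))

    candidates.sort(key=lambda cl: (-len(cl), -_internal_weight(net, cl), cl))
    assigned: set[str] = set()
    clusters: list[frozenset[str]] = []
    for cl in candidates:
        if assigned & set(cl):
            continue
        if _clique_ok(net, cl):
            clusters.append(frozenset(cl))
            assigned |= set(cl)
    for x in net.labels:
        if x not in assigned:
            clusters.append(frozenset([x]))
    return Partition(tuple(clusters), (net.source_metric.name, "clique"))


def modularity(net: FunctionalNetwork, partition: Partition, weighted: bool = True) -> float:
    """Direct evaluation of Newman modularity Q on a partition.

    Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j) with A_ij the
    (weighted) adjacency, k_i the (weighted) degree and m the total edge
    weight. Binary mode ignores the weights.
    """
    labels = net.labels
    n = len(labels)
    pos = {x: i for i, x in enumerate(labels)}
    A = np.zeros((n, n))
    for (u, v), w in net.edges.items():
        a = w if weighted else 1.0
        A[pos[u], pos[v]] = A[pos[v], pos[u]] = a
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    cmap = partition.as_mapping()
    c = np.array([cmap[x] for x in labels])
    same = c[:, None] == c[None, :]
    return float(((A - np.outer(k, k) / two_m) * same).sum() / two_m)


def louvain_partition(
    net: FunctionalNetwork,
    n_runs: int = 1000,
    seed: int = 0,
    weighted: bool = True,
) -> Partition:
    """Best-of-``n_runs`` Louvain partition by directly evaluated Q.

    The heuristic is restarted with seeds derived from ``seed``; the
    returned partition maximizes :func:`modularity` (ties keep the first
    run). Deterministic for fixed (seed, n_runs).
    """
    if not net.labels:
        raise ValueError("empty network")
    g = net.to_networkx()
    weight_key = "weight" if weighted else None
    best: Partition | None = None
    best_q = -np.inf
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s % 2**31) for s in ss.generate_state(n_runs, dtype=np.uint64)]
    for rs in run_seeds:
        comms = nx.community.louvain_communities(g, weight=weight_key, seed=int(rs))
        p = Partition(tuple(frozenset(c) for c in comms), (net.source_metric.name, "louvain"))
        q = modularity(net, p, weighted)
        if q > best_q + 1e-15:
            best_q = q
            best = p
    assert best is not None
    return best
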