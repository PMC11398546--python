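"""Independent reference implementations for verification.

These deliberately avoid the main code paths (numpy refinement, MILP):
naive dict/Counter-based refinement, a brute-force balance check, an
exhaustive repair search enumerating modification subsets in ascending
cost, and a per-cluster-pair decomposition of the balance-only optimum.
They exist to certify the fast implementations on small instances and
are used by the test suite and the acceptance script; they are not meant
for production-size graphs.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Iterable, Mapping, Sequence

from .fibration import Coloring, Connectome
from .partition import Partition
from .repair import RepairProblem

__all__ = [
    "naive_refinement",
    "naive_is_balanced",
    "exhaustive_repair_minimum",
    "decomposed_balance_minimum",
    "random_instance_battery",
]


def random_instance_battery(seed: int, n_instances: int, max_nodes: int = 5):
    """Fixed-seed battery of small random digraphs with random targets.

    Yields ``(Connectome, Coloring)`` pairs: 3..max_nodes nodes, edge
    probability 0.35, a uniformly drawn cluster count with every cluster
    forced non-empty. Used to certify the MILP and the refinement
    machinery against the brute-force references.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n = int(rng.integers(3, max_nodes + 1))
        nodes = tuple(f"v{i}" for i in range(n))
        edges = {}
        for i in range(n):
            for j in range(n):
                if i != j and rng.random() < 0.35:
                    edges[(nodes[i], nodes[j])] = 1.0
        K = int(rng.integers(1, n + 1))
        assign = rng.integers(0, K, size=n)
        for k in range(K):
            if not (assign == k).any():
                assign[int(rng.integers(0, n))] = k
        part = Partition.from_mapping({nodes[i]: int(assign[i]) for i in range(n)})
        yield Connectome(nodes, edges), Coloring(part)


def _in_lists(nodes: Sequence[str], edges: Iterable[tuple[str, str]]) -> dict[str, list[str]]:
    lists: dict[str, list[str]] = {v: [] for v in nodes}
    for (u, v) in edges:
        lists[v].append(u)
    return lists


def naive_is_balanced(
    nodes: Sequence[str], edges: Iterable[tuple[str, str]], clusters: Sequence[frozenset[str]]
) -> bool:
    """Brute-force balance check on an edge set (binary adjacency)."""
    color = {x: k for k, cl in enumerate(clusters) for x in cl}
    lists = _in_lists(nodes, edges)
    for cl in clusters:
        profiles = {
            tuple(sorted(Counter(color[u] for u in lists[v]).items())) for v in cl
        }
        if len(profiles) > 1:
            return False
    return True


def naive_refinement(
    nodes: Sequence[str],
    edges: Iterable[tuple[str, str]],
    seed: Mapping[str, int] | None = None,
) -> Partition:
    """Fixed-point split-by-input-profile refinement, dict/Counter based.

    Returns the coarsest balanced coloring refining ``seed`` (default one
    color). Reference implementation for the fast numpy refinement.
    """
    nodes = list(nodes)
    lists = _in_lists(nodes, edges)
    colors: dict[str, int] = dict(seed) if seed else {v: 0 for v in nodes}
    while True:
        sig: dict[tuple, int] = {}
        new: dict[str, int] = {}
        for v in nodes:
            profile = tuple(sorted(Counter(colors[u] for u in lists[v]).items()))
            key = (colors[v], profile)
            if key not in sig:
                sig[key] = len(sig)
            new[v] = sig[key]
        if len(set(new.values())) == len(set(colors.values())):
            colors = new
            break
        colors = new
    return Partition.from_mapping(colors)


def _coarsest_equals(
    nodes: Sequence[str],
    edges: Iterable[tuple[str, str]],
    target: Coloring,
) -> bool:
    seed: dict[str, int] = {}
    rigid = target.rigid_labels
    next_color = 1
    for i in target.rigid:
        for x in target.partition.clusters[i]:
            seed[x] = next_color
        next_color += 1
    for x in nodes:
        seed.setdefault(x, 0)
    got = naive_refinement(nodes, edges, seed)
    return got.same_partition(target.partition)


def exhaustive_repair_minimum(
    p: RepairProblem,
    require_minimal: bool = False,
    max_cost: float = 12.0,
) -> tuple[float, tuple[tuple[str, str], ...], tuple[tuple[str, str], ...]]:
    """Exhaustive minimum over modification subsets, in ascending cost.

    Enumerates all (removal-count, addition-count) levels sorted by
    ``alpha*k_r + beta*k_a`` and within a level all subsets, accepting the
    first whose repaired edge set is balanced for the target (and, with
    ``require_minimal``, whose coarsest coloring refining the rigid seed
    equals the target). Raises if no solution exists up to ``max_cost``.
    """
    nodes = list(p.connectome.nodes)
    clusters = p.target.partition.clusters
    removable = list(p.removable_edges)
    fixed = [e for e in p.connectome.edges if e not in set(removable)]
    cand = list(p.candidate_edges)
    levels = sorted(
        (
            (p.alpha * kr + p.beta * ka, kr, ka)
            for kr in range(len(removable) + 1)
            for ka in range(len(cand) + 1)
        ),
    )
    for cost, kr, ka in levels:
        if cost > max_cost:
            break
        for rem in itertools.combinations(removable, kr):
            kept = [e for e in removable if e not in set(rem)] + fixed
            for add in itertools.combinations(cand, ka):
                edges = kept + list(add)
                if not naive_is_balanced(nodes, edges, clusters):
                    continue
                if require_minimal and not _coarsest_equals(nodes, edges, p.target):
                    continue
                return float(cost), tuple(sorted(rem)), tuple(sorted(add))
    raise RuntimeError(f"no repair found with cost <= {max_cost}")


def decomposed_balance_minimum(p: RepairProblem) -> float:
    """Balance-only optimum by per-(target-cluster, source-cluster) decomposition.

    Balance constrains, for each target cluster T and source cluster R,
    all members of T to share one in-count c from R; the cheapest way to
    reach a given c decomposes over members (remove surplus in-edges at
    cost alpha each, add missing candidates at cost beta each). The
    global optimum is the sum over (T, R) blocks of the per-block minimum
    over feasible c. Valid for the default (unrestricted) candidate set
    or any candidate set closed per (node, source-cluster) block.
    """
    part = p.target.partition
    cluster_of = part.as_mapping()
    removable = set(p.removable_edges)
    fixed = set(p.connectome.edges) - removable
    cand_by = {}
    for (u, v) in p.candidate_edges:
        cand_by.setdefault((v, cluster_of[u]), 0)
        cand_by[(v, cluster_of[u])] += 1
    rem_by: dict[tuple[str, int], int] = {}
    fix_by: dict[tuple[str, int], int] = {}
    for (u, v) in removable:
        key = (v, cluster_of[u])
        rem_by[key] = rem_by.get(key, 0) + 1
    for (u, v) in fixed:
        key = (v, cluster_of[u])
        fix_by[key] = fix_by.get(key, 0) + 1

    total = 0.0
    for T, members in enumerate(part.clusters):
        for R in range(part.n_clusters):
            best = None
            cmax = max(
                fix_by.get((x, R), 0) + rem_by.get((x, R), 0) + cand_by.get((x, R), 0)
                for x in members
            )
            cmin = max(fix_by.get((x, R), 0) for x in members)  # fixed edges can't go
            for cval in range(0, cmax + 1):
                if cval < cmin:
                    continue
                cost = 0.0
                feasible = True
                for x in members:
                    have = fix_by.get((x, R), 0) + rem_by.get((x, R), 0)
                    if cval <= have:
                        surplus = have - cval
                        if surplus > rem_by.get((x, R), 0):
                            feasible = False
                            break
                        cost += p.alpha * surplus
                    else:
                        need = cval - have
                        if need > cand_by.get((x, R), 0):
                            feasible = False
                            break
                        cost += p.beta * need
                if feasible and (best is None or cost < best):
                    best = cost
            if best is None:
                raise RuntimeError(f"no feasible in-count for block (cluster {T}, source {R})")
            total += best
    return total
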