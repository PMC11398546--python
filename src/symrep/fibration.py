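"""Directed-graph machinery for graph fibrations and balanced colorings.

Houses the connectome container and the structural core of the method:

* balanced-coloring verification — every member of a cluster must receive
  the same number of edges from each cluster;
* coarsest balanced (minimal) coloring by iterative refinement;
* input trees and their isomorphism test — two nodes lie in the same fiber
  iff their rooted trees of iterated in-neighbourhoods are isomorphic;
* base-graph (quotient) construction satisfying the lifting property;
* bilateral collapsing of left/right neuron pairs.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .partition import Partition

__all__ = [
    "Connectome",
    "Coloring",
    "BaseGraph",
    "InputTree",
    "BalanceReport",
    "BalanceViolation",
    "read_connectome",
    "write_connectome",
    "collapse_bilateral",
    "is_balanced",
    "minimal_balanced_coloring",
    "input_tree",
    "input_trees_isomorphic",
    "build_base",
    "normalize_worm_label",
]

Role = str  # "interneuron" | "motorneuron" | "generic"


@dataclass
class Connectome:
    """Directed weighted graph with node roles.

    ``edges`` maps ordered pairs ``(source, target)`` to a non-negative
    weight. Integer weights double as edge multiplicities for balance
    counting; parallel edges are represented this way. ``pre_weights``
    retains pre-binarization weights after bilateral collapsing (used by
    the weighted repair-cost mode).
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    roles: dict[str, Role] = field(default_factory=dict)
    collapsed: bool = False
    pre_weights: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        node_set = set(self.nodes)
        for (u, v), w in self.edges.items():
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not a node: {(u, v)}")
            if w < 0:
                raise ValueError(f"negative weight on edge {(u, v)}: {w}")
        for x in self.roles:
            if x not in node_set:
                raise ValueError(f"role for unknown node {x!r}")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    def role_of(self, node: str) -> Role:
        return self.roles.get(node, "generic")

    def index(self) -> dict[str, int]:
        return {x: i for i, x in enumerate(self.nodes)}

    def weight_matrix(self, mode: str = "multiplicity") -> np.ndarray:
        """Adjacency as an ``n x n`` array, ``W[i, j]`` = weight of edge i->j.

        ``mode="multiplicity"`` keeps integer weights as edge counts,
        ``mode="binary"`` reduces any positive weight to 1.
        """
        idx = self.index()
        W = np.zeros((self.n, self.n))
        for (u, v), w in self.edges.items():
            W[idx[u], idx[v]] = w
        if mode == "binary":
            W = (W > 0).astype(float)
        elif mode == "multiplicity":
            if not np.allclose(W, np.round(W)):
                raise ValueError("multiplicity counting requires integer weights")
            W = np.round(W)
        else:
            raise ValueError(f"unknown counting mode {mode!r}")
        return W

    def in_neighbors(self, v: str) -> list[tuple[str, float]]:
        return [(u, w) for (u, t), w in self.edges.items() if t == v]

    def candidate_edges(self, exclude_targets: Iterable[str] = ()) -> list[tuple[str, str]]:
        """Ordered non-edges excluding self-loops (the addable pairs E^C)."""
        excl = set(exclude_targets)
        return [
            (u, v)
            for u in self.nodes
            for v in self.nodes
            if u != v and v not in excl and (u, v) not in self.edges
        ]

    def copy(self) -> "Connectome":
        return Connectome(
            self.nodes,
            dict(self.edges),
            dict(self.roles),
            self.collapsed,
            dict(self.pre_weights) if self.pre_weights is not None else None,
        )

    def modified(
        self,
        removed: Iterable[tuple[str, str]] = (),
        added: Iterable[tuple[str, str]] = (),
    ) -> "Connectome":
        """Return a copy with the given edges removed / added (weight 1)."""
        edges = dict(self.edges)
        for e in removed:
            edges.pop(tuple(e))
        for e in added:
            e = tuple(e)
            if e in edges:
                raise ValueError(f"edge already present: {e}")
            edges[e] = 1.0
        return Connectome(self.nodes, edges, dict(self.roles), self.collapsed, self.pre_weights)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Connectome):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self.edges == other.edges
            and {x: self.role_of(x) for x in self.nodes}
            == {x: other.role_of(x) for x in other.nodes}
        )


@dataclass(frozen=True)
class Coloring:
    """A partition of connectome nodes, optionally with rigid clusters.

    Rigid clusters (given as indices into ``partition.clusters``) must not
    change membership: in the worm convention each collapsed interneuron
    pair is its own rigid singleton cluster.
    """

    partition: Partition
    rigid: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rigid", tuple(sorted(set(self.rigid))))
        for i in self.rigid:
            if not 0 <= i < self.partition.n_clusters:
                raise ValueError(f"rigid index {i} out of range")

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]], rigid_labels: Iterable[str] = ()) -> "Coloring":
        p = Partition.from_sets(sets)
        rigid_set = set(rigid_labels)
        rigid = tuple(i for i, c in enumerate(p.clusters) if c & rigid_set)
        return cls(p, rigid)

    @property
    def rigid_labels(self) -> frozenset[str]:
        return frozenset(x for i in self.rigid for x in self.partition.clusters[i])

    def covers(self, nodes: Iterable[str]) -> bool:
        return set(nodes) == set(self.partition.labels)


@dataclass(frozen=True)
class BalanceViolation:
    node: str
    source_cluster: int
    observed: float
    expected: float


@dataclass(frozen=True)
class BalanceReport:
    balanced: bool
    violations: tuple[BalanceViolation, ...] = ()

    def __bool__(self) -> bool:
        return self.balanced


def _cluster_onehot(c: Connectome, p: Partition) -> np.ndarray:
    idx = c.index()
    K = p.n_clusters
    M = np.zeros((c.n, K))
    for k, cl in enumerate(p.clusters):
        for x in cl:
            M[idx[x], k] = 1.0
    return M


def in_count_matrix(c: Connectome, p: Partition, mode: str = "multiplicity") -> np.ndarray:
    """``P[i, k]`` = number of edges node ``i`` receives from cluster ``k``."""
    W = c.weight_matrix(mode)
    M = _cluster_onehot(c, p)
    return W.T @ M  # (n, K)


def is_balanced(c: Connectome, coloring: Coloring | Partition, mode: str = "multiplicity") -> BalanceReport:
    """Check the balanced-coloring condition.

    A coloring is balanced iff for every ordered cluster pair (C_i, C_j)
    all members of C_i receive the same number of edges from C_j. The
    report lists every (node, source-cluster) whose in-count deviates from
    its cluster's reference member.
    """
    p = coloring.partition if isinstance(coloring, Coloring) else coloring
    if set(p.labels) != set(c.nodes):
        raise ValueError("coloring does not cover the connectome's nodes")
    P = in_count_matrix(c, p, mode)
    idx = c.index()
    violations: list[BalanceViolation] = []
    for cl in p.clusters:
        members = sorted(cl)
        ref = P[idx[members[0]]]
        for x in members[1:]:
            row = P[idx[x]]
            for k in np.nonzero(row != ref)[0]:
                violations.append(BalanceViolation(x, int(k), float(row[k]), float(ref[k])))
    return BalanceReport(not violations, tuple(violations))


def minimal_balanced_coloring(
    c: Connectome,
    seed_partition: Coloring | Partition | None = None,
    mode: str = "multiplicity",
) -> Coloring:
    """Coarsest balanced coloring refining ``seed_partition``.

    Iteratively splits clusters by each node's profile of in-edge counts
    per current cluster until a fixed point; with the default one-color
    seed this yields the minimal balanced coloring (the fibers). Rigid
    clusters of a seed :class:`Coloring` are pre-split and stay separate.
    """
    if seed_partition is None:
        seed = Partition.from_sets([set(c.nodes)]) if c.n else Partition(())
        rigid_labels: frozenset[str] = frozenset()
    elif isinstance(seed_partition, Coloring):
        seed = seed_partition.partition
        rigid_labels = seed_partition.rigid_labels
    else:
        seed = seed_partition
        rigid_labels = frozenset()
    if c.n == 0:
        return Coloring(Partition(()))
    if set(seed.labels) != set(c.nodes):
        raise ValueError("seed partition does not cover the connectome's nodes")

    idx = c.index()
    W = c.weight_matrix(mode)
    colors = np.zeros(c.n, dtype=int)
    for k, cl in enumerate(seed.clusters):
        for x in cl:
            colors[idx[x]] = k
    while True:
        K = colors.max() + 1
        M = np.zeros((c.n, K))
        M[np.arange(c.n), colors] = 1.0
        P = W.T @ M  # in-counts per current color
        sig = {}
        new = np.empty(c.n, dtype=int)
        for i in range(c.n):
            s = (colors[i], tuple(P[i]))
            if s not in sig:
                sig[s] = len(sig)
            new[i] = sig[s]
        if len(sig) == K and np.array_equal(_canon(new), _canon(colors)):
            break
        colors = new
    p = Partition.from_mapping({x: int(colors[idx[x]]) for x in c.nodes})
    rigid = tuple(i for i, cl in enumerate(p.clusters) if cl & rigid_labels)
    return Coloring(p, rigid)


def _canon(colors: np.ndarray) -> tuple[int, ...]:
    seen: dict[int, int] = {}
    out = []
    for v in colors:
        if int(v) not in seen:
            seen[int(v)] = len(seen)
        out.append(seen[int(v)])
    return tuple(out)


# ---------------------------------------------------------------------------
# input trees

@dataclass(frozen=True)
class InputTree:
    """Rooted layered tree of a node's iterated in-neighbourhoods.

    ``encoding`` is a canonical nested-tuple form: depth-0 trees encode as
    ``()``; at depth d the encoding is the sorted tuple of the in-neighbour
    encodings at depth d-1, one entry per edge (integer multiplicity).
    Equal encodings <=> isomorphic input trees.
    """

    root: str
    depth: int
    encoding: tuple


def input_tree(c: Connectome, v: str, depth: int, mode: str = "multiplicity") -> InputTree:
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if v not in set(c.nodes):
        raise KeyError(v)
    W = c.weight_matrix(mode)
    idx = c.index()
    n = c.n
    in_lists: list[list[int]] = [[] for _ in range(n)]
    for j in range(n):
        for i in np.nonzero(W[:, j])[0]:
            in_lists[j].extend([int(i)] * int(W[i, j]))

    enc: list[tuple] = [() for _ in range(n)]
    for _ in range(depth):
        enc = [tuple(sorted(enc[i] for i in in_lists[j])) for j in range(n)]
    return InputTree(v, depth, enc[idx[v]])


def input_trees_isomorphic(c: Connectome, u: str, v: str, depth: int, mode: str = "multiplicity") -> bool:
    return input_tree(c, u, depth, mode).encoding == input_tree(c, v, depth, mode).encoding


# ---------------------------------------------------------------------------
# base graph

@dataclass(frozen=True)
class BaseGraph:
    """Quotient of a connectome by a balanced coloring.

    One base node per fiber; the multiplicity of base edge ``(B_j, B_i)``
    equals the number of edges any member of fiber i receives from fiber j
    (well defined exactly because the coloring is balanced: the lifting
    property).
    """

    base_nodes: tuple[str, ...]
    multi_edges: dict[tuple[str, str], int]
    fiber_map: dict[str, str]

    def to_connectome(self) -> Connectome:
        """The base as a plain connectome with multiplicity weights."""
        return Connectome(self.base_nodes, {e: float(m) for e, m in self.multi_edges.items()})


def build_base(c: Connectome, coloring: Coloring | Partition, mode: str = "multiplicity") -> BaseGraph:
    """Collapse each fiber to one base node; errors if not balanced."""
    p = coloring.partition if isinstance(coloring, Coloring) else coloring
    report = is_balanced(c, p, mode)
    if not report:
        raise ValueError(f"coloring is not balanced: {report.violations[:5]}")
    P = in_count_matrix(c, p, mode)
    idx = c.index()
    names = [f"B{k}:{min(cl)}" for k, cl in enumerate(p.clusters)]
    edges: dict[tuple[str, str], int] = {}
    for k, cl in enumerate(p.clusters):
        rep = P[idx[min(cl)]]
        for j in np.nonzero(rep)[0]:
            edges[(names[int(j)], names[k])] = int(rep[int(j)])
    fiber_map = {x: names[k] for k, cl in enumerate(p.clusters) for x in cl}
    return BaseGraph(tuple(names), edges, fiber_map)


# ---------------------------------------------------------------------------
# bilateral collapsing

def collapse_bilateral(
    c: Connectome,
    pairs: Mapping[str, tuple[str, str]],
) -> Connectome:
    """Merge left/right members of each pair into one node.

    Binary topology is the OR of the two members' edges per partner
    (weight 1 whether one or both original edges are present); the sum of
    the contributing original weights is retained in ``pre_weights`` for
    the weighted repair-cost mode. Edges between the two members of a pair
    would become self-loops and are dropped with a warning.
    """
    node_set = set(c.nodes)
    members: dict[str, str] = {}
    for name, (left, right) in pairs.items():
        for side in (left, right):
            if side not in node_set:
                raise ValueError(f"pair member {side!r} not in connectome")
            if side in members:
                raise ValueError(f"node {side!r} appears in more than one pair")
            members[side] = name
        if name in node_set and name not in (left, right):
            raise ValueError(f"pair name {name!r} collides with an existing node")

    def rename(x: str) -> str:
        return members.get(x, x)

    new_nodes = []
    seen = set()
    for x in c.nodes:
        nx_ = rename(x)
        if nx_ not in seen:
            seen.add(nx_)
            new_nodes.append(nx_)
    sums: dict[tuple[str, str], float] = {}
    for (u, v), w in c.edges.items():
        nu, nv = rename(u), rename(v)
        if nu == nv:
            warnings.warn(f"edge {(u, v)} becomes a self-loop after collapsing; dropped")
            continue
        sums[(nu, nv)] = sums.get((nu, nv), 0.0) + w
    roles = {rename(x): c.role_of(x) for x in c.nodes}
    return Connectome(
        tuple(new_nodes),
        {e: 1.0 for e in sums},
        roles,
        collapsed=True,
        pre_weights=sums,
    )


# ---------------------------------------------------------------------------
# I/O

def read_connectome(path: str | Path, roles: Mapping[str, Role] | None = None) -> Connectome:
    """Read an edge-list CSV with header ``source,target,weight``.

    Nodes appear in first-seen order; duplicate (source, target) rows are
    an error naming the pair. Roles default to "generic" unless supplied.
    """
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    nodes: list[str] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:3]] != ["source", "target", "weight"]:
            raise ValueError(f"{path}: expected header 'source,target,weight'")
        for ln, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{ln}: malformed row {row!r}")
            u, v, ws = row[0].strip(), row[1].strip(), row[2].strip()
            try:
                w = float(ws)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: bad weight {ws!r}") from exc
            if w < 0:
                raise ValueError(f"{path}:{ln}: negative weight for edge ({u}, {v})")
            if (u, v) in edges:
                raise ValueError(f"{path}:{ln}: duplicate edge ({u}, {v})")
            edges[(u, v)] = w
            for x in (u, v):
                if x not in seen:
                    seen.add(x)
                    nodes.append(x)
    return Connectome(tuple(nodes), edges, dict(roles or {}))


def write_connectome(c: Connectome, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "weight"])
        for (u, v), wt in sorted(c.edges.items()):
            w.writerow([u, v, f"{wt:g}"])


_WORM_ALIASES = {  # zero-padded anatomical names -> compact class names
    **{f"DA0{i}": f"DA{i}" for i in range(1, 10)},
    **{f"VA0{i}": f"VA{i}" for i in range(1, 10)},
    "VA10": "VA10",
    "VA11": "VA11",
    "VA12": "VA12",
}


def normalize_worm_label(label: str) -> str:
    """Map zero-padded worm neuron names (VA01) to compact ones (VA1)."""
    return _WORM_ALIASES.get(label.strip(), label.strip())
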