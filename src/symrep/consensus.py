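"""Consensus clustering of many candidate partitions.

Each candidate partition contributes a binary co-occurrence matrix; the
consensus matrix X averages co-assignment pair by pair over the
partitions containing both labels. X is then clustered hierarchically
with Ward linkage on the dissimilarity 1 - X, and partitions are read off
by cutting the dendrogram: a cut at height h keeps exactly the merges
with height <= h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .partition import Partition

__all__ = [
    "ConsensusMatrix",
    "Dendrogram",
    "co_occurrence",
    "consensus_matrix",
    "ward_dendrogram",
    "ward_cut",
]


@dataclass
class ConsensusMatrix:
    """Pairwise co-assignment frequencies across candidate partitions."""

    labels: tuple[str, ...]
    values: np.ndarray  # in [0, 1]
    n_partitions: int
    counts: np.ndarray | None = None  # pairs' appearance counts

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("consensus matrix must be symmetric")
        if np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")


@dataclass
class Dendrogram:
    """Ward merge tree over consensus labels.

    ``linkage`` is the scipy (n-1, 4) merge array with non-decreasing
    heights; ``leaf_order`` is the optimal-leaf-ordered display order.
    """

    labels: tuple[str, ...]
    linkage: np.ndarray
    leaf_order: tuple[str, ...]

    @property
    def root_height(self) -> float:
        return float(self.linkage[-1, 2]) if len(self.linkage) else 0.0

    def cut(self, cutoff: float) -> Partition:
        """Partition from cutting the tree: merges with height <= cutoff."""
        if cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if len(self.labels) == 1:
            return Partition.from_sets([set(self.labels)], (f"consensus@{cutoff:g}",))
        flat = hierarchy.fcluster(self.linkage, t=cutoff, criterion="distance")
        return Partition.from_mapping(
            {x: int(k) for x, k in zip(self.labels, flat)}, (f"consensus@{cutoff:g}",)
        )


def co_occurrence(p: Partition, labels: Sequence[str]) -> np.ndarray:
    """Binary co-assignment matrix of ``p`` over a label universe.

    Entry (i, j) is 1 iff i and j share a cluster of ``p``; the diagonal
    is 1 for labels covered by ``p`` and 0 otherwise.
    """
    labels = tuple(labels)
    pos = {x: i for i, x in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)))
    for cl in p.clusters:
        ix = [pos[x] for x in cl if x in pos]
        M[np.ix_(ix, ix)] = 1.0
    return M


def consensus_matrix(partitions: Sequence[Partition]) -> ConsensusMatrix:
    """Average co-occurrence over partitions, pair by pair.

    X(i, j) is the mean co-assignment over the partitions containing both
    i and j, mirroring the cohort-averaging denominator used for the
    synchrony matrices. Pairs never observed together get X = 0 with a
    warning.
    """
    if not partitions:
        raise ValueError("no partitions")
    labels = sorted(set().union(*(p.labels for p in partitions)))
    n = len(labels)
    pos = {x: i for i, x in enumerate(labels)}
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for p in partitions:
        present = [pos[x] for x in p.labels]
        ix = np.ix_(present, present)
        counts[ix] += 1
        sums += co_occurrence(p, labels)
    never = (counts == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(f"{int(never.sum()) // 2} label pairs never co-appear; consensus set to 0")
    with np.errstate(invalid="ignore"):
        X = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    np.fill_diagonal(X, 1.0)
    return ConsensusMatrix(tuple(labels), X, len(partitions), counts)


def ward_dendrogram(X: ConsensusMatrix) -> Dendrogram:
    """Ward linkage on the dissimilarity 1 - X with optimal leaf ordering.

    The Lance–Williams Ward update is applied to the precomputed
    dissimilarity directly (no Euclidean embedding first).
    """
    n = len(X.labels)
    D = 1.0 - X.values
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    if n == 1:
        return Dendrogram(X.labels, np.empty((0, 4)), X.labels)
    cond = squareform(D, checks=False)
    Z = hierarchy.linkage(cond, method="ward")
    Z = hierarchy.optimal_leaf_ordering(Z, cond)
    order = tuple(X.labels[i] for i in hierarchy.leaves_list(Z))
    return Dendrogram(X.labels, Z, order)


def ward_cut(X: ConsensusMatrix, cutoff: float) -> Partition:
    """Partition from Ward clustering of 1 - X cut at ``cutoff``."""
    return ward_dendrogram(X).cut(cutoff)
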