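"""Node partitions (clusters of synchrony) and operations on them.

A :class:`Partition` is a disjoint, exhaustive grouping of node labels.
Downstream it plays two roles: a candidate cluster-of-synchrony assignment
produced by functional clustering, and the color classes of a (target)
balanced coloring of the connectome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = ["Partition", "dedup_partitions"]


@dataclass(frozen=True)
class Partition:
    """Disjoint, exhaustive grouping of labels into clusters.

    Parameters
    ----------
    clusters
        Non-empty, pairwise-disjoint label sets. Stored in a canonical
        order (by smallest member label) so that equal set-partitions
        compare equal regardless of construction order.
    provenance
        Free-form tags recording how the partition was obtained,
        e.g. ``("los:0.16", "clique")``.
    """

    clusters: tuple[frozenset[str], ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        clusters = tuple(frozenset(c) for c in self.clusters)
        if any(len(c) == 0 for c in clusters):
            raise ValueError("empty cluster in partition")
        seen: set[str] = set()
        for c in clusters:
            if seen & c:
                raise ValueError(f"overlapping clusters: {sorted(seen & c)}")
            seen |= c
        clusters = tuple(sorted(clusters, key=lambda c: min(c)))
        object.__setattr__(self, "clusters", clusters)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object], provenance: Iterable[str] = ()) -> "Partition":
        """Build from a ``label -> cluster id`` mapping."""
        groups: dict[object, set[str]] = {}
        for label, cid in mapping.items():
            groups.setdefault(cid, set()).add(label)
        return cls(tuple(frozenset(g) for g in groups.values()), tuple(provenance))

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]], provenance: Iterable[str] = ()) -> "Partition":
        return cls(tuple(frozenset(s) for s in sets), tuple(provenance))

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(x for c in self.clusters for x in c)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.clusters)

    def as_mapping(self) -> dict[str, int]:
        """``label -> cluster index`` (canonical cluster order)."""
        return {x: k for k, c in enumerate(self.clusters) for x in c}

    def key(self) -> frozenset[frozenset[str]]:
        """Canonical identity as an unordered set-partition."""
        return frozenset(self.clusters)

    def same_partition(self, other: "Partition") -> bool:
        return self.key() == other.key()

    def restrict(self, labels: Iterable[str]) -> "Partition":
        """Induced partition on a label subset (empty clusters dropped)."""
        keep = set(labels)
        sets = [c & keep for c in self.clusters]
        return Partition(tuple(frozenset(s) for s in sets if s), self.provenance)

    def cluster_of(self, label: str) -> frozenset[str]:
        for c in self.clusters:
            if label in c:
                return c
        raise KeyError(label)

    def with_provenance(self, *tags: str) -> "Partition":
        return Partition(self.clusters, self.provenance + tags)


def dedup_partitions(partitions: Sequence[Partition]) -> list[Partition]:
    """Keep the first occurrence of each distinct set-partition.

    Partitions are compared as unordered set-partitions (cluster labels and
    ordering ignored). Provenance tags of duplicates are merged onto the
    surviving first occurrence.
    """
    out: list[Partition] = []
    index: dict[frozenset[frozenset[str]], int] = {}
    for p in partitions:
        k = p.key()
        if k in index:
            i = index[k]
            merged = out[i].provenance + tuple(t for t in p.provenance if t not in out[i].provenance)
            out[i] = Partition(out[i].clusters, merged)
        else:
            index[k] = len(out)
            out.append(p)
    return out
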