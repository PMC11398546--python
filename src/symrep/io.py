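"""Plain-text I/O for traces, matrices, partitions and repair solutions.

Formats
-------
* Trace CSV: first column ``neuron``, remaining columns the sample times;
  one file per animal.
* Matrix CSV: labels as first row and column; a sidecar ``.meta.json``
  carries the metric; averaged matrices get a ``.counts.csv`` alongside.
* Partition JSON: ``{"clusters": {"0": [...], ...}, "provenance": [...]}``
  (colorings add a ``"rigid"`` cluster-id list).
* Solution JSON: removed/added edge arrays, objective, verification.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fibration import Coloring
from .partition import Partition
from .synchrony import AveragedMatrix, MetricSpec, SynchronyMatrix
from .synthetic import TraceMatrix

__all__ = [
    "write_traces", "read_traces",
    "write_matrix", "read_averaged_matrix",
    "write_partition", "read_partition",
    "write_coloring", "read_coloring",
    "write_solution",
]


def write_traces(tm: TraceMatrix, path: str | Path) -> None:
    times = np.arange(tm.n_time) * tm.dt
    df = pd.DataFrame(tm.values, index=list(tm.neuron_labels), columns=[f"{t:g}" for t in times])
    df.index.name = "neuron"
    df.to_csv(path)


def read_traces(path: str | Path, animal_id: str | None = None) -> TraceMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    times = np.array([float(c) for c in df.columns])
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return TraceMatrix(animal_id or path.stem, tuple(df.index.astype(str)), df.to_numpy(), dt)


def _metric_to_json(metric: MetricSpec) -> dict:
    return {"family": metric.family, "sigma": metric.sigma}


def write_matrix(m: SynchronyMatrix | AveragedMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(m.values, index=list(m.labels), columns=list(m.labels))
    df.to_csv(path)
    meta = {"metric": _metric_to_json(m.metric)}
    if isinstance(m, SynchronyMatrix):
        meta["animal_id"] = m.animal_id
    if isinstance(m, AveragedMatrix):
        pd.DataFrame(m.counts, index=list(m.labels), columns=list(m.labels)).to_csv(
            path.with_suffix(".counts.csv")
        )
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_averaged_matrix(path: str | Path) -> AveragedMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    counts = pd.read_csv(path.with_suffix(".counts.csv"), index_col=0).to_numpy()
    metric = MetricSpec(meta["metric"]["family"], meta["metric"]["sigma"])
    return AveragedMatrix(metric, tuple(df.index.astype(str)), df.to_numpy(), counts)


def write_partition(p: Partition, path: str | Path) -> None:
    data = {
        "clusters": {str(i): sorted(c) for i, c in enumerate(p.clusters)},
        "provenance": list(p.provenance),
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_partition(path: str | Path) -> Partition:
    data = json.loads(Path(path).read_text())
    return Partition.from_sets(
        [set(v) for v in data["clusters"].values()], tuple(data.get("provenance", []))
    )


def write_coloring(c: Coloring, path: str | Path) -> None:
    data = {
        "clusters": {str(i): sorted(cl) for i, cl in enumerate(c.partition.clusters)},
        "provenance": list(c.partition.provenance),
        "rigid": [str(i) for i in c.rigid],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_coloring(path: str | Path) -> Coloring:
    data = json.loads(Path(path).read_text())
    ids = sorted(data["clusters"], key=int)
    sets = [set(data["clusters"][i]) for i in ids]
    rigid_labels = {x for i in data.get("rigid", []) for x in data["clusters"][i]}
    return Coloring.from_sets(sets, rigid_labels)


def write_solution(sol, path: str | Path) -> None:
    data = {
        "removed": [list(e) for e in sol.removed],
        "added": [list(e) for e in sol.added],
        "objective": sol.objective,
        "status": sol.status,
        "mode_used": sol.mode_used,
        "fallback": sol.fallback,
        "verification": {
            "balanced": sol.verification.get("balanced"),
            "minimal": sol.verification.get("minimal"),
        },
        "message": sol.message,
    }
    Path(path).write_text(json.dumps(data, indent=1))
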