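"""End-to-end orchestration: traces -> synchrony -> clusters -> repair -> p-values.

The pipeline mirrors the full structure-function analysis: per-animal
synchrony matrices under a 44-metric bank, cohort averaging with
co-occurrence denominators, functional-network thresholding, clique and
Louvain partitions (88 candidates), consensus co-occurrence, Ward cuts at
a cutoff ladder, MILP repair of the connectome toward each cut partition
over an (alpha, beta) penalty sweep, and a permutation significance test
per cut. The partition with the lowest permutation p-value (ties broken
by lowest modification percentage) is selected as the optimal solution.

Every intermediate artifact is written under the output directory with a
SHA-256 checksum recorded in the run manifest; reruns with the same
config and seed reproduce the checksums exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .clustering import clique_synchronization, louvain_partition, threshold_matrix
from .consensus import consensus_matrix, ward_dendrogram
from .fibration import Coloring, Connectome, read_connectome
from .partition import Partition, dedup_partitions
from .repair import RepairProblem, modification_percentage, penalty_sweep
from .significance import permutation_pvalue
from .synchrony import cohort_average, compute_metric, metric_bank
from .synthetic import TraceMatrix

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One config for the whole pipeline.

    ``trace_dir`` and ``connectome_path`` are read at run start; for
    programmatic use a cohort and connectome may be passed in memory
    instead. The global seed derives every stochastic stage (Louvain
    restarts, permutation draws).
    """

    out_dir: str | Path = "symrep_run"
    trace_dir: str | Path | None = None
    connectome_path: str | Path | None = None
    cohort: Sequence[TraceMatrix] | None = None
    connectome: Connectome | None = None
    methods: tuple[str, ...] = ("clique", "louvain")
    threshold_rule: str = "global-min-max"
    louvain_runs: int = 200
    cutoffs: tuple[float, ...] = (1.0, 0.85, 0.77, 0.58, 0.55, 0.50, 0.40, 0.34)
    alphas: tuple[float, ...] = (1.0,)
    betas: tuple[float, ...] = (1.0, 2.0)
    unbalancing_mode: str = "strict"
    cost_mode: str = "unit"
    n_permutations: int = 200
    permutation_denominator: str = "fixed-n"
    rigid_roles: tuple[str, ...] = ("interneuron",)
    seed: int = 0

    def resolve_inputs(self) -> tuple[list[TraceMatrix], Connectome]:
        if self.cohort is None:
            if self.trace_dir is None:
                raise FileNotFoundError("config has neither a cohort nor a trace_dir")
            tdir = Path(self.trace_dir)
            if not tdir.is_dir():
                raise FileNotFoundError(f"trace_dir {tdir} does not exist")
            cohort = [sio.read_traces(f) for f in sorted(tdir.glob("*.csv"))]
            if not cohort:
                raise FileNotFoundError(f"no trace CSVs in {tdir}")
        else:
            cohort = list(self.cohort)
        if self.connectome is None:
            if self.connectome_path is None:
                raise FileNotFoundError("config has neither a connectome nor a connectome_path")
            cpath = Path(self.connectome_path)
            if not cpath.is_file():
                raise FileNotFoundError(f"connectome {cpath} does not exist")
            connectome = read_connectome(cpath)
        else:
            connectome = self.connectome
        return cohort, connectome

    def serializable(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["trace_dir"] = str(self.trace_dir) if self.trace_dir else None
        d["connectome_path"] = str(self.connectome_path) if self.connectome_path else None
        d["cohort"] = None if self.cohort is None else f"<in-memory, {len(self.cohort)} animals>"
        d["connectome"] = None if self.connectome is None else "<in-memory>"
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _target_coloring(candidate: Partition, connectome: Connectome, rigid_roles: tuple[str, ...]) -> Coloring:
    """Candidate clusters + rigid singletons for rigid-role nodes."""
    rigid_nodes = [x for x in connectome.nodes if connectome.role_of(x) in rigid_roles]
    sets = [set(c) - set(rigid_nodes) for c in candidate.clusters]
    sets = [s for s in sets if s]
    covered = set().union(*sets) if sets else set()
    for x in connectome.nodes:
        if x in rigid_nodes:
            sets.append({x})
        elif x not in covered:
            warnings.warn(f"node {x} not covered by candidate partition; made a singleton")
            sets.append({x})
    return Coloring.from_sets(sets, rigid_nodes)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    cohort, connectome = config.resolve_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict = {"config": config.serializable(), "stages": {}}

    def record(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha256(path)

    # stage 1: per-animal synchrony matrices + cohort averages
    bank = metric_bank()
    averaged = []
    (out / "matrices").mkdir(exist_ok=True)
    for metric in bank:
        per_animal = [compute_metric(tm, metric) for tm in cohort]
        avg = cohort_average(per_animal)
        averaged.append(avg)
        path = out / "matrices" / f"avg_{metric.name.replace(':', '_')}.csv"
        sio.write_matrix(avg, path)
        record(path)
    manifest["stages"]["synchrony"] = {"n_metrics": len(bank), "n_animals": len(cohort),
                                       "n_averaged_matrices": len(averaged)}

    # stage 2: functional networks and candidate partitions
    rng = np.random.SeedSequence(config.seed)
    louvain_seeds = [int(s % 2**31) for s in rng.generate_state(len(averaged), dtype=np.uint64)]
    candidates: list[Partition] = []
    for i, avg in enumerate(averaged):
        net = threshold_matrix(avg, config.threshold_rule)
        if "clique" in config.methods:
            candidates.append(clique_synchronization(net))
        if "louvain" in config.methods:
            candidates.append(louvain_partition(net, config.louvain_runs, louvain_seeds[i]))
    unique = dedup_partitions(candidates)
    (out / "partitions").mkdir(exist_ok=True)
    for i, p in enumerate(unique):
        path = out / "partitions" / f"candidate_{i:03d}.json"
        sio.write_partition(p, path)
        record(path)
    manifest["stages"]["clustering"] = {
        "n_candidate_partitions": len(candidates),
        "n_unique_partitions": len(unique),
    }

    # stage 3: consensus matrix + Ward cuts
    X = consensus_matrix(candidates)
    dfX = pd.DataFrame(X.values, index=list(X.labels), columns=list(X.labels))
    xpath = out / "consensus.csv"
    dfX.to_csv(xpath)
    record(xpath)
    dend = ward_dendrogram(X)
    dpath = out / "dendrogram.json"
    dpath.write_text(json.dumps({
        "labels": list(dend.labels),
        "merges": dend.linkage.tolist(),
        "leaf_order": list(dend.leaf_order),
    }, indent=1))
    record(dpath)
    cut_partitions: list[tuple[float, Partition]] = []
    seen_keys = set()
    (out / "cuts").mkdir(exist_ok=True)
    for cutoff in config.cutoffs:
        p = dend.cut(cutoff)
        if p.key() in seen_keys:
            continue
        seen_keys.add(p.key())
        cut_partitions.append((cutoff, p))
        path = out / "cuts" / f"cut_{cutoff:g}.json"
        sio.write_partition(p, path)
        record(path)
    manifest["stages"]["consensus"] = {
        "n_partitions_fused": X.n_partitions,
        "cutoffs": list(config.cutoffs),
        "n_distinct_cuts": len(cut_partitions),
    }

    # stage 4: repair sweep + permutation significance per cut
    perm_seeds = [int(s % 2**31) for s in np.random.SeedSequence([config.seed, 101]).generate_state(
        max(len(cut_partitions), 1), dtype=np.uint64)]
    rows = []
    (out / "solutions").mkdir(exist_ok=True)
    for j, (cutoff, candidate) in enumerate(cut_partitions):
        target = _target_coloring(candidate, connectome, config.rigid_roles)
        base_problem = RepairProblem(connectome, target, unbalancing_mode=config.unbalancing_mode)
        records = penalty_sweep(base_problem, config.betas, config.alphas, config.cost_mode)
        ok = [r for r in records if r["status"] == "optimal"]
        if not ok:
            warnings.warn(f"cutoff {cutoff}: no optimal solution in sweep; skipped")
            continue
        best = min(ok, key=lambda r: (r["modification_pct"], r["beta"], r["alpha"]))
        problem = RepairProblem(connectome, target, best["alpha"], best["beta"],
                                unbalancing_mode=config.unbalancing_mode)
        perm = permutation_pvalue(
            problem, config.n_permutations, perm_seeds[j], config.permutation_denominator,
        )
        sol = best["solution"]
        spath = out / "solutions" / f"cutoff_{cutoff:g}.json"
        sio.write_solution(sol, spath)
        record(spath)
        n_rigid = len(target.rigid)
        rows.append({
            "cutoff": cutoff,
            "partition": [sorted(c) for c in candidate.clusters],
            "measure": "consensus",
            "modified_pct": best["modification_pct"],
            "alpha": best["alpha"],
            "beta": best["beta"],
            "fibers": target.partition.n_clusters - n_rigid,
            "p_value": perm.p_value,
            "objective": best["objective"],
            "minimal": bool(sol.verification.get("minimal", False)),
        })
    summary = pd.DataFrame(rows)
    spath = out / "summary.csv"
    summary.to_csv(spath, index=False)
    record(spath)

    selected = None
    if rows:
        selected = min(rows, key=lambda r: (r["p_value"], r["modified_pct"]))
    manifest["stages"]["repair"] = {"n_cuts_repaired": len(rows)}
    manifest["selected"] = selected
    manifest["artifacts"] = artifacts
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, default=float))
    return manifest
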