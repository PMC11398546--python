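"""Synthetic fibration-symmetric graphs, admissible dynamics, trace cohorts.

Everything downstream of raw imaging is testable without external data:
this module plants a known fiber partition in a directed graph (by lifting
a random base graph), simulates an admissible ODE on it (so that nodes in
one fiber provably synchronize), and emits a multi-animal cohort of trace
matrices with per-animal missing neurons — the same observational
structure as a multi-worm calcium-imaging study.

The concrete admissible model is a saturating-coupling rate equation

    dx_i/dt = -x_i + tanh(g * sum_j A_ij x_j) + u_f(i)(t)  (+ noise)

with a slow square-wave drive ``u_f`` shared by all members of fiber f,
mimicking discrete command states. A Kuramoto variant is provided. Only
admissibility matters for the theory (coupling dictated by the edges and
identical intrinsic dynamics within a fiber); the drive differs across
fibers so that fibers are functionally distinguishable.

Numerical note: each node's coupling sum is accumulated over its in-edges
sorted by source fiber, with padding aligned within a fiber. Same-fiber
nodes therefore sum elementwise-equal value sequences, so with zero noise
and shared initial conditions their trajectories are *bit-identical*, and
a lifted graph reproduces its base trajectories exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .fibration import Connectome, is_balanced, minimal_balanced_coloring
from .partition import Partition

__all__ = [
    "TraceMatrix",
    "PlantedGraph",
    "SimulationConfig",
    "generate_fibered_graph",
    "simulate_dynamics",
    "make_cohort",
    "standard_synthetic_study",
]


@dataclass
class TraceMatrix:
    """One animal's neuron-by-time activity record."""

    animal_id: str
    neuron_labels: tuple[str, ...]
    values: np.ndarray  # (neurons, time)
    dt: float

    def __post_init__(self) -> None:
        self.neuron_labels = tuple(self.neuron_labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.neuron_labels):
            raise ValueError("values must be (n_neurons, n_time)")
        if len(set(self.neuron_labels)) != len(self.neuron_labels):
            raise ValueError("duplicate neuron labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite trace values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_labels)

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.values[self.neuron_labels.index(label)]

    def subset(self, labels: Sequence[str]) -> "TraceMatrix":
        keep = [self.neuron_labels.index(x) for x in labels]
        return TraceMatrix(self.animal_id, tuple(labels), self.values[keep], self.dt)


@dataclass(frozen=True)
class PlantedGraph:
    """Directed graph with a planted fiber partition and its generating base.

    ``base_edges`` maps (source fiber, target fiber) to the multiplicity
    with which every member of the target fiber receives edges from the
    source fiber (the lifting property by construction).
    """

    connectome: Connectome
    planted_partition: Partition
    fibers: tuple[tuple[str, ...], ...]  # fiber order used by the simulator
    base_edges: dict[tuple[int, int], int]

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.connectome.nodes

    def fiber_of(self) -> dict[str, int]:
        return {x: f for f, fib in enumerate(self.fibers) for x in fib}

    def base_planted(self) -> "PlantedGraph":
        """The base graph, itself as a PlantedGraph with singleton fibers.

        Fiber order is preserved, so simulating the base with matched
        initial conditions reproduces each fiber's trajectory exactly.
        """
        names = tuple(f"b{f}" for f in range(len(self.fibers)))
        edges = {
            (names[g], names[f]): float(m) for (g, f), m in self.base_edges.items()
        }
        base = Connectome(names, edges)
        part = Partition.from_sets([{x} for x in names])
        return PlantedGraph(base, part, tuple((x,) for x in names),
                            dict(self.base_edges))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the admissible-ODE simulation (Euler–Maruyama)."""

    model: str = "saturating-coupling"  # or "kuramoto"
    noise_sd: float = 0.05
    duration: float = 60.0
    dt: float = 0.1
    seed: int = 0
    initial_condition_mode: str = "shared-within-fiber"  # or "random"
    coupling_strength: float = 0.5

    def __post_init__(self) -> None:
        if self.model not in ("saturating-coupling", "kuramoto"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.initial_condition_mode not in ("shared-within-fiber", "random"):
            raise ValueError(f"unknown IC mode {self.initial_condition_mode!r}")
        if not (self.noise_sd >= 0 and np.isfinite(self.noise_sd)):
            raise ValueError("noise_sd must be finite and >= 0")
        if not (0 < self.dt < self.duration):
            raise ValueError("require 0 < dt < duration")


def generate_fibered_graph(
    n_fibers: int,
    fiber_sizes: Sequence[int],
    base_density: float,
    seed: int,
    allow_self_loops: bool = False,
    max_attempts: int = 200,
) -> PlantedGraph:
    """Construct a base graph and lift it so each base node becomes a fiber.

    For every base edge g->f, each node of fiber f receives exactly one
    edge from a (random) member of fiber g, so the planted partition is a
    balanced coloring by construction. The base is resampled until the
    coarsest balanced coloring of the lift equals the planted partition
    (fibers distinguishable by their base in-profiles).
    """
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    fiber_sizes = tuple(int(s) for s in fiber_sizes)
    if len(fiber_sizes) != n_fibers:
        raise ValueError("fiber_sizes length must equal n_fibers")
    if any(s < 1 for s in fiber_sizes):
        raise ValueError("every fiber must contain at least one node")
    if not 0 <= base_density <= 1:
        raise ValueError("base_density must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    K = n_fibers
    fibers = tuple(
        tuple(f"f{f}n{i}" for i in range(fiber_sizes[f])) for f in range(K)
    )
    nodes = tuple(x for fib in fibers for x in fib)
    planted = Partition.from_sets([set(fib) for fib in fibers])

    last_err = "no attempt made"
    for _ in range(max_attempts):
        base_edges: dict[tuple[int, int], int] = {}
        for g in range(K):
            for f in range(K):
                if g == f and fiber_sizes[f] < 2 and not allow_self_loops:
                    continue
                if rng.random() < base_density:
                    base_edges[(g, f)] = 1
        edges: dict[tuple[str, str], float] = {}
        ok = True
        for (g, f), mult in base_edges.items():
            for target in fibers[f]:
                pool = [x for x in fibers[g] if x != target]
                if g == f and fiber_sizes[f] == 1:
                    pool = [target] if allow_self_loops else []
                if len(pool) < mult:
                    ok = False
                    break
                sources = rng.choice(len(pool), size=mult, replace=False)
                for s in sources:
                    edges[(pool[int(s)], target)] = edges.get((pool[int(s)], target), 0.0) + 1.0
            if not ok:
                break
        if not ok:
            last_err = "lift infeasible for sampled base"
            continue
        graph = Connectome(nodes, edges)
        if not is_balanced(graph, planted):
            last_err = "planted partition not balanced (internal error)"
            continue
        if minimal_balanced_coloring(graph).partition.same_partition(planted):
            return PlantedGraph(graph, planted, fibers, base_edges)
        last_err = "coarsest coloring coarser than planted partition"
    raise RuntimeError(
        f"could not generate a distinguishable fibered graph in {max_attempts} "
        f"attempts (last: {last_err}); raise base_density or change the seed"
    )


def _fiber_drive(model: str, f: int, t: np.ndarray) -> np.ndarray:
    """Slow square-wave command drive, distinct per fiber, deterministic."""
    amp = 0.6 + 0.15 * f
    period = 12.0 * (1.0 + 0.35 * f)
    phase = 0.8 * f
    return amp * np.sign(np.sin(2.0 * np.pi * t / period + phase))


def _aligned_in_lists(graph: PlantedGraph) -> tuple[np.ndarray, np.ndarray]:
    """Per-node in-edge index lists sorted by source fiber, padded.

    Returns ``(idx, mask)`` of shape (n, max_deg); padding points at an
    extra zero slot (index n). Same-fiber nodes get equal-length lists
    with segments aligned fiber by fiber, which makes their coupling sums
    bit-identical whenever the network state is fiber-synchronous.
    """
    c = graph.connectome
    index = c.index()
    fiber_of = graph.fiber_of()
    W = c.weight_matrix("multiplicity")
    n = c.n
    lists: list[list[int]] = []
    for j in range(n):
        entries: list[tuple[int, int]] = []
        for i in np.nonzero(W[:, j])[0]:
            entries.extend([(fiber_of[c.nodes[int(i)]], int(i))] * int(W[int(i), j]))
        entries.sort()
        lists.append([i for _, i in entries])
    max_deg = max((len(l) for l in lists), default=0)
    idx = np.full((n, max(max_deg, 1)), n, dtype=int)
    mask = np.zeros((n, max(max_deg, 1)))
    for j, l in enumerate(lists):
        idx[j, : len(l)] = l
        mask[j, : len(l)] = 1.0
    return idx, mask


def simulate_dynamics(graph: PlantedGraph, config: SimulationConfig) -> TraceMatrix:
    """Euler–Maruyama integration of the admissible model on the graph.

    The trace records the state at t = 0, dt, ..., (T-1) dt with
    T = round(duration / dt). Fixed seed => bit-identical output.
    """
    c = graph.connectome
    if c.n == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(config.seed)
    n = c.n
    T = int(round(config.duration / config.dt))
    fiber_of = graph.fiber_of()
    fiber_idx = np.array([fiber_of[x] for x in c.nodes])
    idx, mask = _aligned_in_lists(graph)

    if config.initial_condition_mode == "shared-within-fiber":
        fic = rng.standard_normal(len(graph.fibers)) * 0.5
        x = fic[fiber_idx].copy()
    else:
        x = rng.standard_normal(n) * 0.5

    out = np.empty((n, T))
    out[:, 0] = x
    g = config.coupling_strength
    sq_dt = np.sqrt(config.dt)
    times = np.arange(T) * config.dt
    drives = np.stack(
        [_fiber_drive(config.model, f, times) for f in range(len(graph.fibers))]
    )  # (K, T)
    x_ext = np.empty(n + 1)
    x_ext[n] = 0.0
    for step in range(1, T):
        x_ext[:n] = x
        if config.model == "saturating-coupling":
            coupling = x_ext[idx].sum(axis=1)
            dxdt = -x + np.tanh(g * coupling) + drives[fiber_idx, step - 1]
        else:  # kuramoto
            omega = 1.0 + 0.2 * fiber_idx
            terms = np.sin(x_ext[idx] - x[:, None]) * mask
            dxdt = omega + g * terms.sum(axis=1) + 0.3 * drives[fiber_idx, step - 1]
        x = x + config.dt * dxdt
        if config.noise_sd > 0:
            x = x + config.noise_sd * sq_dt * rng.standard_normal(n)
        if not np.all(np.isfinite(x)):
            raise RuntimeError(f"non-finite state at integration step {step}")
        out[:, step] = x
    return TraceMatrix("sim", c.nodes, out, config.dt)


def make_cohort(
    graph: PlantedGraph,
    n_animals: int,
    missing_fraction: float,
    config: SimulationConfig,
    max_regenerations: int = 100,
) -> list[TraceMatrix]:
    """Simulate a cohort; each animal omits a random neuron subset.

    Per-animal seeds are derived deterministically from ``config.seed``
    and the animal index, so identical inputs reproduce the cohort
    exactly. The missing sets are redrawn (deterministically) until every
    neuron is observed in at least one animal; failure to achieve
    coverage raises an explicit error.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must lie in [0, 1)")
    nodes = graph.nodes
    n = len(nodes)
    n_missing = int(round(missing_fraction * n))
    mask_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, 17]))
    for attempt in range(max_regenerations):
        missing_sets = [
            set(mask_rng.choice(n, size=n_missing, replace=False).tolist())
            for _ in range(n_animals)
        ]
        observed: set[int] = set()
        for m in missing_sets:
            observed |= set(range(n)) - m
        if observed == set(range(n)):
            break
        warnings.warn(f"cohort draw {attempt} left a neuron unobserved; redrawing")
    else:
        raise RuntimeError(
            f"missing_fraction={missing_fraction} left some neuron unobserved in "
            f"all animals after {max_regenerations} redraws"
        )

    cohort = []
    for a in range(n_animals):
        sub_seed = int(np.random.SeedSequence([int(config.seed) % 2**31, a]).generate_state(1)[0] % 2**31)
        tm = simulate_dynamics(graph, replace(config, seed=sub_seed))
        keep = [nodes[i] for i in range(n) if i not in missing_sets[a]]
        tm = tm.subset(keep)
        tm.animal_id = f"animal{a:02d}"
        cohort.append(tm)
    return cohort


def standard_synthetic_study(seed: int = 0, noise_sd: float = 0.05):
    """The package's reference study conditions.

    A 7-fiber planted connectome (18 neurons, fiber sizes 3,3,3,2,2,3,2),
    an 8-animal cohort with 20% of neurons missing per animal, and
    low-noise saturating-coupling dynamics — the synthetic analogue of an
    8-worm backward-locomotion imaging cohort.

    Returns ``(graph, cohort, config)``.
    """
    graph = generate_fibered_graph(
        n_fibers=7,
        fiber_sizes=(3, 3, 3, 2, 2, 3, 2),
        base_density=0.55,
        seed=seed,
    )
    config = SimulationConfig(noise_sd=noise_sd, duration=60.0, dt=0.1, seed=seed)
    cohort = make_cohort(graph, n_animals=8, missing_fraction=0.2, config=config)
    return graph, cohort, config
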