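# Methods

## Balanced colorings, fibers, and what the package computes

A partition 𝒞 = {C_1, …, C_K} of a directed graph's nodes is a *balanced
coloring* when, for every ordered cluster pair (C_i, C_j), all members of
C_i receive the same number of edges from C_j. The clusters of the
coarsest balanced coloring are the graph's *fibers*: nodes with
isomorphic input trees, which any admissible dynamical system (one whose
coupling terms are dictated by the edges, with identical intrinsic
dynamics within a fiber) drives into exact trajectory synchrony. The
package's structural core computes and certifies these objects three
independent ways:

* **Refinement** (`fibration.minimal_balanced_coloring`): iterative
  split-by-input-profile from a seed coloring (default one color) to a
  fixed point, vectorized over a counts matrix. This yields the coarsest
  balanced coloring refining the seed. Rigid seed clusters are pre-split
  and tracked through the refinement.
* **Input trees** (`fibration.input_tree`): canonical nested-tuple
  encodings of iterated in-neighbourhoods; two nodes share a fiber iff
  their encodings agree at depth |V|.
* **A naive dict/Counter reference** (`oracle.naive_refinement`) used
  only for certification.

Integer edge weights are treated as multiplicities in balance counts
(`mode="multiplicity"`), with a `"binary"` mode for collapsed
connectomes; the repair MILP always works on the binary adjacency, which
matches the binarized collapsed connectome it is meant for. Only one edge
type (chemical synapses) is exercised; the machinery is per-edge-type by
construction but no heterogeneous-type mode is exposed.

## The repair MILP

Given G = (V, E), addable pairs E^C (default: every ordered non-edge, no
self-loops), and a target coloring 𝒮, the model minimizes
α Σ_{E} r_ij + β Σ_{E^C} a_ij subject to, for every target cluster and
every source cluster, equal post-repair in-counts among the cluster's
members (imposed between consecutive members, which chains to all
pairs). Optional constraints: a minimum in-degree of one per node (off by
default, flagged in solution metadata), forbidden removals/additions.

*Unbalancing constraints.* Binary indicators s_pq^R certify that node p
receives strictly more influence from cluster R than node q:
d_R(p) − d_R(q) ≥ s_pq^R − n·s_qp^R (and the mirror), s_pq^R + s_qp^R ≤ 1,
with big-M n = |V|. Two distinctness forms exist: the *relaxed* form
(some cluster witnesses a difference for every cross-cluster pair — a
condition implied by minimality, so it never cuts off a minimal
solution) and a *strict* form that additionally restricts how the pair's
own clusters may act as witnesses. Because balance already forces every
member of a cluster to share its influence profile, the pair constraints
are imposed on one representative node per cluster pair; this shrinks
the model without changing its optima.

Both forms are necessary but not sufficient for true minimality (the
target being the coarsest balanced coloring of the repaired graph), and
the strict form can even exclude genuinely minimal optima. `solve_repair`
therefore treats solver output as a proposal only:

1. every incumbent is re-verified combinatorially — balance by the
   balanced-coloring checker, minimality by refinement seeded with the
   rigid clusters;
2. in strict mode, a non-minimal incumbent is excluded by a no-good cut
   on its (r, a) assignment and the model re-solved (bounded loop);
3. the strict result is certified against a lower bound, or failing
   that against the relaxed form solved with the same minimality cuts —
   which computes exactly the minimum over minimally-colored outcomes;
   if the strict form cannot reach it, the certified solution is
   returned with `fallback=True`.

*Lower bound.* The balance constraints decompose over (target cluster,
source cluster) blocks: all members must share one in-count c from each
source cluster, and the cheapest way to reach a given c decomposes over
members (α per surplus removal, β per missing addition). Minimizing over
c per block and summing gives the exact balance-only optimum in closed
form — used both as an optimality certificate and to screen permutation
nulls (below). It is disabled when the min-in-degree option couples the
blocks.

The backend is HiGHS branch-and-bound via `scipy.optimize.milp` with
zero MIP gap; runs are deterministic on a given platform. The contract
is the optimal objective value — ties among optimal edge sets are
solver-dependent and deliberately not part of the contract.

Modification percentages divide by |E| of the source connectome: unit
mode counts every change as 1; weighted mode charges removals their
pre-binarization weight (kept by `collapse_bilateral`) and additions 1.

## Synchrony metrics and their conventions

* LoS is evaluated exactly as the time-averaged Gaussian kernel; σ grid
  0.01 … 0.20 in 0.005 steps (39 values). In exact arithmetic LoS ∈
  (0, 1] with equality iff pointwise-identical series and is
  non-decreasing in σ; in floating point very small σ with large
  differences can underflow to exactly 0, and sub-1e-8 differences round
  to 1 — the tests account for both.
* Covariance uses the unbiased 1/(T−1) estimator; Kendall is τ-b
  (tie-corrected); Spearman is Pearson on ranks.
* Distance correlation is the standard biased sample estimator
  (double-centered distance matrices); the per-series centered matrices
  are precomputed once per animal, which makes the all-pairs bank cheap.
  The implementation is cross-checked against an independent library
  estimator in the tests.
* Zero-variance series get correlation value 0 with a warning — matrices
  stay total without fabricating association. Covariance is left as
  computed (0 against a constant series).
* Cohort averages divide each pair's sum by the number of animals
  containing both neurons; pairs never co-observed stay undefined (NaN,
  count 0). The consensus matrix uses the same per-pair denominator over
  partitions; pairs never co-covered get X = 0 (maximal dissimilarity)
  with a warning. Raw covariance is used for thresholding; an optional
  rescale is deliberately not applied by default.

## Functional networks and clustering

Two thresholding rules are implemented and recorded in the network
metadata rather than silently chosen. The default, parameter-free rule
keeps every entry at least τ = min over neurons of each neuron's largest
averaged entry — every neuron retains its strongest link. The
alternative percolation rule adds edges in decreasing weight (ties in
lexicographic label order) until the graph is one connected component.

Clique synchronization accepts a fully connected clique of N nodes when
its internal weight sum is ≥ N(N−1)/2 times every edge from a member to
an outside neighbour; outside neighbourhoods are always evaluated on the
full network. Candidates are swept in decreasing size, then decreasing
internal weight, accepted cliques removing their nodes; leftovers become
singletons. Full clique enumeration is used when feasible, with a
maximal-clique shrink fallback on very dense graphs; every emitted
clique is re-certified post hoc by an independent checker in the tests.

Louvain restarts the networkx heuristic `n_runs` times (seeds derived
from one seed) and keeps the partition with the highest modularity,
where the reported Q is always our own direct evaluation of weighted
Newman modularity (binary mode available); the functional network is
weighted, so weighted A_ij and weighted degrees are the default.

Consensus clustering applies the Lance–Williams Ward update to the
precomputed dissimilarity 1 − X directly (no Euclidean embedding first —
the common hierarchical-clustering default, recorded in metadata), with
optimal leaf ordering for display. "Cut at h" keeps merges of height
≤ h; ties are broken by merge order. Cuts are nested: raising the cutoff
never splits a cluster.

## The synthetic study

The generator lifts a random base digraph (edge probability
`base_density`; self-loops only where the fiber can absorb them) so that
each base node becomes a fiber and every base edge g→f gives each member
of fiber f exactly one in-edge from fiber g — the lifting property by
construction. Bases are resampled until the coarsest balanced coloring
of the lift equals the planted partition, so fibers are distinguishable
by structure alone.

The concrete admissible model is a saturating-coupling rate equation
dx_i/dt = −x_i + tanh(g Σ_j A_ij x_j) + u_f(i)(t) (+ σ_n dW), integrated
by Euler–Maruyama; a Kuramoto variant is included. The square-wave drive
u_f is shared within a fiber (preserving the symmetry that forces
within-fiber synchrony) but differs across fibers in amplitude, period
and phase, mimicking discrete command states and making fibers
functionally distinguishable — without it, metrics could not separate
fibers whose structural inputs produce similar trajectories.

Coupling sums are accumulated over in-edges sorted by source fiber with
aligned padding, so same-fiber nodes sum elementwise-equal floating-point
sequences: at zero noise with shared initial conditions, within-fiber
trajectories are bit-identical, and the base graph (multiplicities
expanded as repeated indices) reproduces each fiber's trajectory
exactly. This is a deliberate numerical design, not an approximation
claim. With random initial conditions, coupling strength 0.3 on the test
graphs makes the system contractive enough that within-fiber spread
falls below 1e-6 after the transient.

Reference study conditions (`standard_synthetic_study`): 7 fibers of
sizes (3, 3, 3, 2, 2, 3, 2) — 18 neurons, base density 0.55; 8 animals;
20% of neurons missing per animal (redrawn deterministically until every
neuron is observed somewhere); noise SD 0.05; duration 60 at dt 0.1
(600 samples). These mirror a realistic multi-animal imaging cohort of a
small motor circuit: a handful of synchrony groups, single-digit animal
counts, and per-animal dropout from segmentation and field-of-view
limits. What the synthetic cohort does *not* emulate: slow calcium-
indicator kernels, bleaching and motion artefacts, behavioral-state
non-stationarity, and annotation errors in neuron identity — so passing
tests certify the inference machinery, not robustness to those real-data
effects.

## Permutation significance

Null partitions shuffle labels while preserving the cluster-size
multiset; rigid clusters are untouched. The p-value is the fraction of
nulls whose optimal modification count is ≤ the observed one, divided by
n (`fixed-n`) or by the number of nulls with a comparable solution
(`valid-only`); both denominators are exposed since either convention is
defensible. Comparison uses the unit modification count by default, with
a weighted-objective flag. Raw counts are reported without a 1/(n+1)
floor; a zero count reports p = 0 with a logged caveat. All-singleton
and one-cluster targets are invariant under every permutation, so their
p-values are exactly 1 — the expected U-shape endpoints; the minimum
over cutoffs is taken without multiple-testing correction (a deliberate
mirror of the selection rule; the p-values are selection scores, not
calibrated error rates).

Permutation solves are cached by canonical set-partition, and under the
fixed-n denominator a null whose closed-form balance-only lower bound
already exceeds the observed statistic is counted as not-as-good without
a MILP solve; this changes nothing in the p-value and makes 200-null
tests essentially free when the observed cost is small.

## Pipeline and problem sizes

The orchestrated run writes every artifact with a SHA-256 checksum into
a manifest; identical config + seed reproduces identical checksums. Per
candidate cut, a penalty sweep (defaults α = 1, β ∈ {1, 2}) picks the
solution with the lowest modification percentage, a permutation test
scores it, and the final selection is minimum p-value with ties broken
by lowest modification percentage.

Default desk-scale sizes, chosen so a complete run takes well under a
minute on one CPU: 100 Louvain restarts per functional network in
pipeline runs (the standalone default is 1000; on 18-node networks the
restart distribution saturates far earlier), 200 permutations per cut,
and the 8-cutoff ladder (1.0 … 0.34). The verification battery uses 200
random digraphs of ≤ 5 nodes — small enough for exhaustive
subset-enumeration oracles, large enough to exercise every constraint
family.

## Known limitations

* The MILP operates on binary adjacency; weighted balance constraints
  are out of scope.
* Strict-mode exactness relies on the no-good-cut loop; pathological
  targets that admit many cheap non-minimal repairs could exhaust the
  cut budget (default 200), in which case the solution is returned with
  `minimal=False` rather than silently accepted.
* Ward-on-dissimilarity is a convention, not a theorem; with strongly
  non-Euclidean consensus matrices other linkages may order merges
  differently.
* Permutation p-values are Monte-Carlo estimates; at n = 200 the
  resolution is 0.005 and a reported 0 means "< 1/200".
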