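"""Pairwise synchrony metrics and cohort averaging.

Two metric classes are used: the Level of Synchronicity (LoS),

    LoS_ij = (1/T) * sum_t exp(-(V_i(t) - V_j(t))^2 / (2 sigma^2)),

a time-averaged Gaussian kernel of instantaneous signal differences whose
bandwidth sigma sets the benchmark for "closeness" of two samples, and a
family of correlation measures (Pearson, Spearman, Kendall tau-b,
distance correlation, covariance). The standard bank is 39 LoS variants
(sigma from 0.01 to 0.20 in 0.005 steps) plus the five correlation
measures: 44 metrics.

Per-animal matrices are averaged across a cohort pair by pair, dividing
each summed entry by the number of animals in which both neurons were
observed together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .synthetic import TraceMatrix

__all__ = [
    "MetricSpec",
    "SynchronyMatrix",
    "AveragedMatrix",
    "compute_los",
    "sigma_grid",
    "compute_metric",
    "cohort_average",
    "metric_bank",
]

_CORRELATION_FAMILIES = ("pearson", "spearman", "kendall", "distance-correlation", "covariance")


@dataclass(frozen=True)
class MetricSpec:
    """A synchrony metric: LoS at a given sigma, or a correlation family."""

    family: str
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.family == "los":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("LoS requires a positive sigma")
        elif self.family in _CORRELATION_FAMILIES:
            if self.sigma is not None:
                raise ValueError(f"{self.family} takes no sigma")
        else:
            raise ValueError(f"unknown metric family {self.family!r}")

    @property
    def name(self) -> str:
        return f"los:{self.sigma:g}" if self.family == "los" else self.family


@dataclass
class SynchronyMatrix:
    """Symmetric pairwise metric values for one animal."""

    metric: MetricSpec
    labels: tuple[str, ...]
    values: np.ndarray
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("synchrony matrix must be symmetric")


@dataclass
class AveragedMatrix:
    """Cohort-averaged matrix with pairwise co-occurrence counts.

    ``values[i, j]`` is defined (non-NaN) only where ``counts[i, j] > 0``.
    """

    metric: MetricSpec
    labels: tuple[str, ...]
    values: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.labels)
        if self.values.shape != (n, n) or self.counts.shape != (n, n):
            raise ValueError("values/counts must be square over labels")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")


def sigma_grid() -> np.ndarray:
    """The 39-value LoS bandwidth grid: 0.01, 0.015, ..., 0.20."""
    return np.round(np.arange(0.01, 0.2001, 0.005), 4)


def metric_bank() -> list[MetricSpec]:
    """The standard 44-metric bank: 39 LoS + 5 correlation measures."""
    bank = [MetricSpec("los", float(s)) for s in sigma_grid()]
    bank += [MetricSpec(f) for f in _CORRELATION_FAMILIES]
    return bank


def compute_los(x: Sequence[float], y: Sequence[float], sigma: float) -> float:
    """Level of Synchronicity between two equal-length series.

    Returns a value in (0, 1]; 1 exactly iff the series are pointwise
    identical. Non-decreasing in sigma for fixed series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be equal-length non-empty 1-D series")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = x - y
    return float(np.mean(np.exp(-(d * d) / (2.0 * sigma * sigma))))


def _los_matrix(values: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (values[:, None, :] - values[None, :, :]) ** 2
    return np.exp(-d2 / (2.0 * sigma * sigma)).mean(axis=2)


def _distance_correlation_bank(values: np.ndarray) -> np.ndarray:
    """Pairwise distance correlation (Székely biased sample estimator).

    Per-series double-centered distance matrices are precomputed once;
    dCov^2(x, y) is then the mean elementwise product.
    """
    n, T = values.shape
    centered = np.empty((n, T, T))
    for i in range(n):
        D = squareform(pdist(values[i, :, None], metric="euclidean"))
        centered[i] = D - D.mean(axis=0, keepdims=True) - D.mean(axis=1, keepdims=True) + D.mean()
    out = np.eye(n)
    dvar = np.array([(centered[i] * centered[i]).mean() for i in range(n)])
    for i in range(n):
        for j in range(i + 1, n):
            dcov2 = (centered[i] * centered[j]).mean()
            denom = np.sqrt(dvar[i] * dvar[j])
            r = np.sqrt(max(dcov2, 0.0) / denom) if denom > 0 else 0.0
            out[i, j] = out[j, i] = r
    return out


def compute_metric(traces: TraceMatrix, metric: MetricSpec) -> SynchronyMatrix:
    """Pairwise synchrony matrix for one animal under one metric.

    Zero-variance series under a correlation family yield a flagged value
    of 0 for the affected pairs (with a warning) rather than NaN.
    """
    V = traces.values
    n, T = V.shape
    if n < 2:
        raise ValueError("need at least two neurons")
    if metric.family != "los" and T < 2:
        raise ValueError("correlation families need at least two time points")

    if metric.family == "los":
        M = _los_matrix(V, float(metric.sigma))
        np.fill_diagonal(M, 1.0)
        return SynchronyMatrix(metric, traces.neuron_labels, _symmetrize(M), traces.animal_id)

    sd = V.std(axis=1)
    degenerate = np.nonzero(sd == 0)[0]
    if degenerate.size and metric.family != "covariance":
        warnings.warn(
            f"zero-variance series for neurons {[traces.neuron_labels[i] for i in degenerate]}; "
            f"their {metric.family} values are recorded as 0"
        )

    if metric.family == "covariance":
        M = np.cov(V, ddof=1)
        M = np.atleast_2d(M)
    elif metric.family == "pearson":
        M = _safe_corrcoef(V, sd)
    elif metric.family == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 1, V)
        M = _safe_corrcoef(ranks, ranks.std(axis=1))
    elif metric.family == "kendall":
        M = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                if sd[i] == 0 or sd[j] == 0:
                    tau = 0.0
                else:
                    tau = stats.kendalltau(V[i], V[j]).statistic
                    if not np.isfinite(tau):
                        tau = 0.0
                M[i, j] = M[j, i] = tau
    elif metric.family == "distance-correlation":
        M = _distance_correlation_bank(V)
        M[degenerate, :] = 0.0
        M[:, degenerate] = 0.0
        np.fill_diagonal(M, 1.0)
        M[degenerate, degenerate] = 1.0
    else:  # pragma: no cover - guarded by MetricSpec
        raise ValueError(metric.family)
    if metric.family != "covariance":
        np.fill_diagonal(M, 1.0)
    return SynchronyMatrix(metric, traces.neuron_labels, _symmetrize(M), traces.animal_id)


def _safe_corrcoef(V: np.ndarray, sd: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.corrcoef(V)
    M = np.atleast_2d(M)
    bad = np.nonzero(sd == 0)[0]
    M[bad, :] = 0.0
    M[:, bad] = 0.0
    M[np.isnan(M)] = 0.0
    return M


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def cohort_average(matrices: Sequence[SynchronyMatrix]) -> AveragedMatrix:
    """Average per-animal matrices over the cohort, pair by pair.

    Entry (i, j) is the sum of the metric over the animals containing both
    i and j, divided by that co-occurrence count; entries with count 0 are
    NaN (undefined). All matrices must share one MetricSpec.
    """
    if not matrices:
        raise ValueError("no matrices to average")
    metric = matrices[0].metric
    if any(m.metric != metric for m in matrices):
        raise ValueError("all matrices must share the same metric")
    labels: list[str] = []
    for m in matrices:
        for x in m.labels:
            if x not in labels:
                labels.append(x)
    labels_t = tuple(sorted(labels))
    n = len(labels_t)
    pos = {x: i for i, x in enumerate(labels_t)}
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for m in matrices:
        ix = np.array([pos[x] for x in m.labels])
        sums[np.ix_(ix, ix)] += m.values
        counts[np.ix_(ix, ix)] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AveragedMatrix(metric, labels_t, values, counts)
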