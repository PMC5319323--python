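"""Normalized differences, the h-statistic, weights and weighted histograms.

The primary compatibility statistic is the uncertainty-normalized difference
between two measurements of the same quantity::

    z_ij = |x_i - x_j| / sqrt(u_i**2 + u_j**2)

When the reported plus and minus uncertainties are asymmetric, each
measurement contributes the uncertainty of the side *towards* the other
member of the pair (for ``x_a < x_b``: ``u_a_plus`` and ``u_b_minus``).

Variants: a covariance-aware denominator ``sqrt(u_i**2 - 2 cov + u_j**2)``
for correlated pairs, and a linear combination ``u_i + u_j`` appropriate for
Cauchy-distributed errors (Cauchy widths add linearly).

Pairs are weighted by one of three schemes: Q gives each quantity total
weight 1, M (the default) gives each quantity total weight equal to its
number of measurements, and P gives every pair weight 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import MeasurementRecord, QuantitySeries

__all__ = [
    "PairStatistic",
    "WeightedHistogram",
    "HStatistic",
    "z_quadrature",
    "z_covariance",
    "z_linear",
    "weighted_mean",
    "h_statistic",
    "enumerate_pairs",
    "default_bin_edges",
    "build_histogram",
    "empirical_ccdf",
    "weighted_quantile",
    "i_squared",
]


@dataclass(frozen=True)
class PairStatistic:
    """One normalized difference with its weight and (optional) time gap."""

    z: float
    weight: float
    quantity_id: str = ""
    id_a: str | None = None
    id_b: str | None = None
    year_gap: float | None = None
    rel_unc_ratio: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.z) and math.isfinite(self.weight)):
            raise ValueError("z and weight must be finite")


@dataclass(frozen=True)
class HStatistic:
    """Deviation of one measurement from its quantity's weighted mean."""

    h: float
    record_id: str | None
    quantity_id: str


@dataclass
class WeightedHistogram:
    """Binned density of z with per-bin (bootstrap) uncertainties.

    ``densities`` are probability per unit z over ``bin_edges``;
    ``counts`` are the per-bin sums of pair weights; mass beyond the last
    edge is collected in ``overflow_mass`` so that the total probability
    (finite bins plus overflow) is 1.
    """

    bin_edges: np.ndarray
    densities: np.ndarray
    uncertainties: np.ndarray
    total_weight: float
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    overflow_mass: float = 0.0
    overflow_weight: float = 0.0
    #: bin-to-bin covariance of the densities (e.g. across bootstrap
    #: replicates); bins are strongly correlated because one measurement
    #: enters many pairs, so fits should propagate this when present.
    bin_covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        self.densities = np.asarray(self.densities, dtype=float)
        self.uncertainties = np.asarray(self.uncertainties, dtype=float)
        if self.counts is None:
            self.counts = np.zeros_like(self.densities)

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_probability(self) -> float:
        """Finite-bin probability plus overflow mass; 1 after normalization."""
        return float(np.sum(self.densities * self.widths) + self.overflow_mass)


def _side_uncertainties(a: MeasurementRecord, b: MeasurementRecord) -> tuple[float, float]:
    """Per-record uncertainties on the side towards the other pair member.

    When the values tie the side is undefined; the average of the two sides
    is used (z is 0 regardless).
    """
    if a.value < b.value:
        return a.u_plus, b.u_minus
    if a.value > b.value:
        return a.u_minus, b.u_plus
    return a.u_symmetric, b.u_symmetric


def z_quadrature(a: MeasurementRecord, b: MeasurementRecord) -> float:
    """|x_a - x_b| / sqrt(u_a**2 + u_b**2) with the asymmetric-side rule."""
    u_a, u_b = _side_uncertainties(a, b)
    denom = math.hypot(u_a, u_b)
    if denom <= 0:
        raise ValueError("zero combined uncertainty")
    return abs(a.value - b.value) / denom


def z_covariance(a: MeasurementRecord, b: MeasurementRecord, cov: float) -> float:
    """Normalized difference for correlated measurements.

    Denominator sqrt(u_a**2 - 2*cov + u_b**2); reduces to
    :func:`z_quadrature` at cov = 0, and perfect anticorrelation
    (cov = -u**2 at equal u) reduces z by a factor sqrt(2).
    """
    u_a, u_b = _side_uncertainties(a, b)
    arg = u_a * u_a - 2.0 * cov + u_b * u_b
    if arg <= 0:
        raise ValueError(f"non-positive denominator argument {arg}")
    return abs(a.value - b.value) / math.sqrt(arg)


def z_linear(a: MeasurementRecord, b: MeasurementRecord) -> float:
    """|x_a - x_b| / (u_a + u_b): linear combination for Cauchy errors."""
    u_a, u_b = _side_uncertainties(a, b)
    denom = u_a + u_b
    if denom <= 0:
        raise ValueError("zero combined uncertainty")
    return abs(a.value - b.value) / denom


def weighted_mean(series: QuantitySeries) -> tuple[float, float]:
    """Inverse-variance weighted mean and its uncertainty.

    Uses symmetrized uncertainties ``(u_plus + u_minus)/2``.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    x = np.array([m.value for m in series.measurements])
    u = np.array([m.u_symmetric for m in series.measurements])
    if np.any(u <= 0):
        raise ValueError("zero uncertainty in weighted mean")
    w = 1.0 / (u * u)
    sw = w.sum()
    return float((x * w).sum() / sw), float(1.0 / math.sqrt(sw))


def h_statistic(record: MeasurementRecord, series: QuantitySeries) -> HStatistic:
    """|x_i - x_bar| / sqrt(u_i**2 + u_xbar**2).

    The weighted mean includes the record itself (the conventional form,
    even though the record then contributes to both terms).
    """
    x_bar, u_bar = weighted_mean(series)
    u = record.u_symmetric
    h = abs(record.value - x_bar) / math.hypot(u, u_bar)
    return HStatistic(h=h, record_id=record.record_id, quantity_id=series.quantity_id)


def _pair_weight(n: int, scheme: str) -> float:
    n_pairs = n * (n - 1) // 2
    if scheme == "Q":
        return 1.0 / n_pairs
    if scheme == "M":
        return n / n_pairs
    if scheme == "P":
        return 1.0
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def _relative_uncertainty(m: MeasurementRecord) -> float | None:
    if m.value == 0:
        return None
    return m.u_symmetric / abs(m.value)


def enumerate_pairs(
    series: QuantitySeries, scheme: str = "M", variant: str = "quadrature",
) -> list[PairStatistic]:
    """All N(N-1)/2 unordered pairs of an eligible series with weights.

    variant selects the z definition (``quadrature`` or ``linear``).
    ``year_gap`` and ``rel_unc_ratio`` (newer/older relative uncertainty;
    ties in year give ratio 1) are filled when both years are present;
    records with value 0 have undefined relative uncertainty and leave the
    ratio unset.
    """
    n = len(series)
    if n < 2:
        return []
    zfun = {"quadrature": z_quadrature, "linear": z_linear}[variant]
    w = _pair_weight(n, scheme)
    out: list[PairStatistic] = []
    ms = series.measurements
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ms[i], ms[j]
            gap = ratio = None
            if a.year is not None and b.year is not None:
                gap = abs(a.year - b.year)
                newer, older = (a, b) if a.year > b.year else (b, a)
                if a.year == b.year:
                    r_new = r_old = 1.0
                else:
                    r_new, r_old = _relative_uncertainty(newer), _relative_uncertainty(older)
                if r_new is not None and r_old is not None and r_old > 0:
                    ratio = r_new / r_old
            out.append(PairStatistic(
                z=zfun(a, b), weight=w, quantity_id=series.quantity_id,
                id_a=a.record_id, id_b=b.record_id,
                year_gap=gap, rel_unc_ratio=ratio,
            ))
    return out


def default_bin_edges(z_max: float = 20.0) -> np.ndarray:
    """Uniform 0.25-wide bins on [0, 5], geometrically widening to z_max.

    Heavy tails need wide high-z bins to keep nonzero occupancy; mass beyond
    z_max goes to the overflow.
    """
    uniform = np.arange(0.0, 5.0 + 1e-12, 0.25)
    geom = np.geomspace(5.0, z_max, 9)[1:]
    return np.concatenate([uniform, geom])


def _as_arrays(pairs: Iterable[PairStatistic]) -> tuple[np.ndarray, np.ndarray]:
    z = np.array([p.z for p in pairs], dtype=float)
    w = np.array([p.weight for p in pairs], dtype=float)
    return z, w


def build_histogram(
    pairs: Sequence[PairStatistic], bin_edges: np.ndarray | None = None,
) -> WeightedHistogram:
    """Weighted density histogram of z, normalized to total probability 1.

    The normalization includes the overflow mass beyond the last edge, so
    uniform rescaling of all weights leaves the histogram unchanged.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to histogram")
    z, w = _as_arrays(pairs)
    return histogram_from_arrays(z, w, bin_edges)


def histogram_from_arrays(
    z: np.ndarray, w: np.ndarray, bin_edges: np.ndarray | None = None,
) -> WeightedHistogram:
    """Array-based core of :func:`build_histogram`."""
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    if z.size == 0:
        raise ValueError("no pairs to histogram")
    counts, _ = np.histogram(z, bins=bin_edges, weights=w)
    overflow_weight = float(w[z >= bin_edges[-1]].sum())
    total = float(w.sum())
    widths = np.diff(bin_edges)
    densities = counts / total / widths
    return WeightedHistogram(
        bin_edges=bin_edges, densities=densities,
        uncertainties=np.zeros_like(densities), total_weight=total,
        counts=counts, overflow_mass=overflow_weight / total,
        overflow_weight=overflow_weight,
    )


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Weighted quantile; ties broken towards the lower value.

    The quantile is the smallest value whose cumulative weight reaches
    q * total.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, q * cum[-1], side="left"))
    return float(v[min(idx, len(v) - 1)])


def empirical_ccdf(
    pairs: Sequence[PairStatistic], thresholds: Sequence[float],
) -> tuple[np.ndarray, float]:
    """Weighted exceedance fractions P(z > threshold) and the weighted z_0.95."""
    if len(pairs) == 0:
        raise ValueError("no pairs")
    z, w = _as_arrays(pairs)
    total = w.sum()
    exceed = np.array([w[z > t].sum() / total for t in thresholds])
    return exceed, weighted_quantile(z, w, 0.95)


def i_squared(series: QuantitySeries) -> float:
    """Heterogeneity inconsistency index I^2 = max(0, 1 - (N-1)/chi2_c)."""
    from .systematics import chi2_consistency  # local import avoids a cycle

    n = len(series)
    if n < 2:
        raise ValueError("need at least 2 measurements")
    chi2 = chi2_consistency(series)
    if chi2 <= 0:
        return 0.0
    return max(0.0, 1.0 - (n - 1) / chi2)
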