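"""Time-evolution diagnostics of measurement uncertainty and agreement.

Covers: the distribution of relative uncertainty u/|x|; the median
newer/older relative-uncertainty ratio versus publication-year gap (with a
halving-time estimate); per-measurement improvement factors against the
best previous measurement of the same quantity; and the weighted median z
versus time gap (a rising trend signals bandwagon-style correlation between
contemporaneous measurements, a flat one their absence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import MeasurementRecord, QuantitySeries
from .pairs import PairStatistic, WeightedHistogram, weighted_quantile

__all__ = [
    "TrendTable",
    "relative_uncertainty_hist",
    "uncertainty_ratio_trend",
    "improvement_factor",
    "median_improvement",
    "median_z_vs_gap",
]

#: Default publication-gap binning: 5-year bins up to 50 years.
DEFAULT_GAP_EDGES = np.arange(0.0, 55.0, 5.0)


@dataclass(frozen=True)
class TrendTable:
    """Per-time-bin median statistic."""

    centers: np.ndarray
    medians: np.ndarray
    counts: np.ndarray
    statistic: str


def relative_uncertainty_hist(
    measurements: Iterable[MeasurementRecord],
    bin_width: float = 0.25,
) -> tuple[WeightedHistogram, int]:
    """Density histogram over log10(u/|x|); returns (hist, n_zero_excluded).

    Records with value exactly 0 have undefined relative uncertainty; they
    are counted and excluded.
    """
    log_rel, n_zero = [], 0
    for m in measurements:
        if m.value == 0:
            n_zero += 1
            continue
        log_rel.append(math.log10(m.u_symmetric / abs(m.value)))
    if not log_rel:
        raise ValueError("no records with nonzero value")
    arr = np.array(log_rel)
    lo = math.floor(arr.min() / bin_width) * bin_width
    hi = math.ceil(arr.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 1e-9, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    dens = counts / counts.sum() / np.diff(edges)
    hist = WeightedHistogram(
        bin_edges=edges, densities=dens, uncertainties=np.zeros_like(dens),
        total_weight=float(len(arr)), counts=counts.astype(float))
    return hist, n_zero


def _binned_weighted_median(
    gaps: np.ndarray, values: np.ndarray, weights: np.ndarray,
    edges: np.ndarray, statistic: str,
) -> TrendTable:
    centers, medians, counts = [], [], []
    idx = np.digitize(gaps, edges) - 1
    for b in range(len(edges) - 1):
        sel = idx == b
        if not np.any(sel):
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        medians.append(weighted_quantile(values[sel], weights[sel], 0.5))
        counts.append(int(sel.sum()))
    return TrendTable(np.array(centers), np.array(medians),
                      np.array(counts), statistic)


def uncertainty_ratio_trend(
    pairs: Sequence[PairStatistic],
    gap_edges: np.ndarray | None = None,
) -> tuple[TrendTable, float]:
    """Median newer/older relative-uncertainty ratio per year-gap bin.

    Also returns the halving time (years for the median ratio to reach 1/2)
    from a log-linear fit of the bin medians; +inf when uncertainties do not
    shrink with time.
    """
    if gap_edges is None:
        gap_edges = DEFAULT_GAP_EDGES
    dated = [p for p in pairs
             if p.year_gap is not None and p.rel_unc_ratio is not None]
    if not dated:
        raise ValueError("no dated pairs with relative-uncertainty ratios")
    gaps = np.array([p.year_gap for p in dated])
    ratios = np.array([p.rel_unc_ratio for p in dated])
    weights = np.array([p.weight for p in dated])
    table = _binned_weighted_median(gaps, ratios, weights, gap_edges,
                                    "median rel-uncertainty ratio (newer/older)")
    ok = table.medians > 0
    if ok.sum() >= 2:
        slope = np.polyfit(table.centers[ok], np.log2(table.medians[ok]), 1,
                           w=np.sqrt(table.counts[ok]))[0]
        halving = -1.0 / slope if slope < 0 else math.inf
    else:
        halving = math.nan
    return table, float(halving)


def improvement_factor(series: QuantitySeries) -> list[float]:
    """u_best_previous / u_new for each measurement after the first.

    Measurements are taken in publication order; a factor above 1 means the
    new measurement improved on the best existing uncertainty.
    """
    dated = [m for m in series.measurements if m.year is not None]
    if len(dated) < 2:
        raise ValueError("need at least 2 dated measurements")
    dated.sort(key=lambda m: m.year)
    factors = []
    best = dated[0].u_symmetric
    for m in dated[1:]:
        factors.append(best / m.u_symmetric)
        best = min(best, m.u_symmetric)
    return factors


def median_improvement(quantities: Iterable[QuantitySeries]) -> float:
    """Dataset median of all per-measurement improvement factors."""
    factors: list[float] = []
    for q in quantities:
        try:
            factors.extend(improvement_factor(q))
        except ValueError:
            continue
    if not factors:
        raise ValueError("no dated series")
    return float(np.median(factors))


def median_z_vs_gap(
    pairs: Sequence[PairStatistic],
    gap_edges: np.ndarray | None = None,
) -> TrendTable:
    """Pair-weighted median z per publication-gap bin."""
    if gap_edges is None:
        gap_edges = DEFAULT_GAP_EDGES
    dated = [p for p in pairs if p.year_gap is not None]
    if not dated:
        raise ValueError("no dated pairs")
    gaps = np.array([p.year_gap for p in dated])
    z = np.array([p.z for p in dated])
    w = np.array([p.weight for p in dated])
    return _binned_weighted_median(gaps, z, w, gap_edges, "median z")
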