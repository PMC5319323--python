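"""Monte-Carlo deconvolution from pair differences to individual errors.

The observed z-distribution describes *differences* of measurements.  Except
in the Cauchy and Normal limits, differences of Student's-t variates are not
exactly t-distributed, so the individual-measurement error distribution is
recovered by simulation: artificial measurements are generated from a
t(nu_x) scaled by sigma_x times each reported uncertainty, combined into
pairs exactly like the real analysis, and (nu_x, sigma_x) adjusted until the
artificial z-histogram best matches the observed one (chi-squared-style
distance in the observed bins).

Common random numbers: one set of uniform draws is transformed through the
t quantile function at every candidate nu_x, so the search surface is smooth
and a derivative-free optimizer can refine a coarse log-grid scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core import QuantitySeries
from .pairs import WeightedHistogram

__all__ = [
    "DeconvolutionConfig",
    "DeconvolutionResult",
    "template_from_quantities",
    "simulate_pairs",
    "deconvolve",
]


@dataclass(frozen=True)
class DeconvolutionConfig:
    seed: int = 0
    min_pair_factor: int = 20      # simulated pairs >= factor * observed pairs
    max_pairs: int = 1_000_000
    nu_bounds: tuple[float, float] = (0.3, 100.0)
    sigma_bounds: tuple[float, float] = (0.05, 10.0)
    grid_size: tuple[int, int] = (12, 10)


@dataclass(frozen=True)
class DeconvolutionResult:
    nu_x: float
    sigma_x: float
    match_score: float
    n_iterations: int
    converged: bool


def template_from_quantities(
    quantities: Sequence[QuantitySeries],
) -> list[np.ndarray]:
    """Per-quantity arrays of symmetrized reported uncertainties."""
    return [np.array([m.u_symmetric for m in q.measurements])
            for q in quantities if q.eligible]


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


class _PairSimulator:
    """Reusable simulator with frozen uniform draws (common random numbers).

    True values are 0 without loss of generality (z is location invariant).
    """

    def __init__(self, template: Sequence[np.ndarray], n_copies: int, seed: int,
                 scheme: str = "M"):
        rng = np.random.default_rng(seed)
        self.template = [np.asarray(u, dtype=float) for u in template]
        self.n_copies = n_copies
        total_meas = sum(len(u) for u in self.template)
        self.uniforms = rng.random((n_copies, total_meas))
        # precompute per-quantity slices, pair index arrays and weights
        self.slices, self.pairs, self.weights, self.u_comb = [], [], [], []
        start = 0
        for u in self.template:
            n = len(u)
            i, j = _pair_indices(n)
            n_pairs = len(i)
            if scheme == "M":
                w = n / n_pairs
            elif scheme == "Q":
                w = 1.0 / n_pairs
            elif scheme == "P":
                w = 1.0
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
            self.slices.append(slice(start, start + n))
            self.pairs.append((i, j))
            self.weights.append(np.full(n_pairs, w))
            self.u_comb.append(np.hypot(u[i], u[j]))
            start += n

    def z_values(self, nu_x: float, sigma_x: float) -> tuple[np.ndarray, np.ndarray]:
        """Simulated (z, weight) arrays for all copies of the template."""
        t_draws = stats.t.ppf(self.uniforms, df=nu_x)
        zs, ws = [], []
        for sl, (i, j), w, uc, u in zip(
                self.slices, self.pairs, self.weights, self.u_comb, self.template):
            errs = u * sigma_x * t_draws[:, sl]          # (copies, n)
            dx = np.abs(errs[:, i] - errs[:, j])         # (copies, n_pairs)
            zs.append((dx / uc).ravel())
            ws.append(np.tile(w, self.n_copies))
        return np.concatenate(zs), np.concatenate(ws)


def simulate_pairs(
    quantities_template: Sequence[np.ndarray],
    nu_x: float,
    sigma_x: float,
    seed: int = 0,
    scheme: str = "M",
    n_copies: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated pair (z, weight) arrays for a template of reported u's.

    Each artificial measurement is ``u_i * sigma_x * T`` with T a unit-scale
    Student's t(nu_x) variate; pairs use the same weighting scheme as the
    real analysis.  Deterministic given *seed*.
    """
    if sigma_x == 0.0:
        sim = _PairSimulator(quantities_template, n_copies, seed, scheme)
        z, w = sim.z_values(nu_x=1.0, sigma_x=1.0)
        return np.zeros_like(z), w
    return _PairSimulator(quantities_template, n_copies, seed, scheme).z_values(
        nu_x, sigma_x)


def deconvolve(
    observed_hist: WeightedHistogram,
    quantities_template: Sequence[np.ndarray],
    config: DeconvolutionConfig | None = None,
    scheme: str = "M",
) -> DeconvolutionResult:
    """Best-matching individual-error parameters (nu_x, sigma_x).

    Coarse scan on a log-parameter grid followed by Nelder-Mead refinement;
    the match score is the chi-squared-style distance between simulated and
    observed bin densities using the observed bin uncertainties.  Flagged
    non-converged when the optimum sticks to the search-domain boundary.
    """
    if config is None:
        config = DeconvolutionConfig()
    use = observed_hist.uncertainties > 0
    if use.sum() < 3:
        raise ValueError("observed histogram needs >= 3 bins with uncertainties")
    b_obs = observed_hist.densities[use]
    u_obs = observed_hist.uncertainties[use]
    edges = observed_hist.bin_edges
    widths = np.diff(edges)

    n_obs_pairs = sum(len(u) * (len(u) - 1) // 2 for u in quantities_template)
    if n_obs_pairs == 0:
        raise ValueError("empty template")
    n_copies = max(1, min(config.min_pair_factor,
                          int(config.max_pairs // n_obs_pairs)))
    sim = _PairSimulator(quantities_template, n_copies, config.seed, scheme)

    n_eval = 0

    def score(log_params: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        nu_x, sigma_x = np.exp(log_params)
        z, w = sim.z_values(nu_x, sigma_x)
        counts, _ = np.histogram(z, bins=edges, weights=w)
        dens = counts / w.sum() / widths
        return float(np.sum(((dens[use] - b_obs) / u_obs) ** 2))

    lo = np.log([config.nu_bounds[0], config.sigma_bounds[0]])
    hi = np.log([config.nu_bounds[1], config.sigma_bounds[1]])
    g_nu, g_sig = config.grid_size
    grid_nu = np.linspace(lo[0], hi[0], g_nu)
    grid_sig = np.linspace(lo[1], hi[1], g_sig)
    best_p, best_s = None, np.inf
    for ln in grid_nu:
        for ls in grid_sig:
            s = score(np.array([ln, ls]))
            if s < best_s:
                best_p, best_s = np.array([ln, ls]), s

    res = optimize.minimize(
        score, best_p, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200})
    p = np.clip(res.x, lo, hi)
    nu_x, sigma_x = np.exp(p)
    # stuck on the boundary of the searchable domain, or a best match that
    # is still grossly incompatible with the observation => no real optimum
    at_edge = bool(np.any(p <= lo + 1e-6) or np.any(p >= hi - 1e-6))
    incompatible = res.fun / max(int(use.sum()), 1) > 25.0
    return DeconvolutionResult(
        nu_x=float(nu_x), sigma_x=float(sigma_x),
        match_score=float(res.fun), n_iterations=n_eval,
        converged=bool(res.success) and not at_edge and not incompatible,
    )
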