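# Methods

## The compatibility statistic

All uncertainties are first normalized to 68.3%-coverage standard
uncertainties: quoted components (statistical, systematic, unspecified) are
combined in quadrature, expanded intervals are divided by their coverage
factor k, and 95% confidence intervals by the two-sided Normal factor
1.959964.  The Normal factor is used even for intervals that may not be
Normal; no better convention is available without per-record information.

A quantity enters the analysis only with at least five independent
measurements.  Records flagged as non-independent can be removed with an
exclusion list, after which eligibility is re-evaluated.

For measurements x_i ± u_i of one quantity, every unordered pair contributes

    z_ij = |x_i − x_j| / sqrt(u_i² + u_j²).

When the plus and minus uncertainties differ, each record contributes the
side *towards* the other member (for x_i < x_j: u_i⁺ and u_j⁻); when the
values tie, the side is undefined and the mean of the two sides is used
(z = 0 regardless).  Two variants are provided: a covariance-aware
denominator sqrt(u_i² − 2cov + u_j²) for correlated pairs, and the linear
combination u_i + u_j appropriate when errors are Cauchy (Cauchy widths add
linearly; at equal uncertainties z_linear = z_quadrature/√2, and the fitted
ν is essentially unchanged while σ shrinks by about that factor).

Weighting schemes: M (default) gives each quantity total weight equal to
its number of measurements — a 10-measurement quantity yields 45 pairs of
weight 10/45; Q gives each quantity total weight 1; P gives every pair unit
weight.  The h-statistic |x_i − x̄| / sqrt(u_i² + u_x̄²), with x̄ the
inverse-variance weighted mean (computed including the record itself, as is
conventional), is provided as a pair-free alternative; symmetrized
uncertainties (u⁺ + u⁻)/2 are used wherever a single u is needed.

## Histogram, bootstrap and fit

z ≥ 0 values are histogrammed with 0.25-wide bins on [0, 5] widening
geometrically to 20, plus an overflow; the density is normalized so that
total probability including overflow is 1, making it invariant under
uniform weight rescaling.  Heavy tails need the wide high-z bins to keep
nonzero occupancy.

Per-bin uncertainties come from a bootstrap that draws whole quantities
with replacement (1000 replicates by default), re-histogramming and
re-normalizing each replicate; the per-bin standard deviation across
replicates is u_Bi.  Resampling measurements instead of quantities would
require bias corrections for missing or duplicated measurements within a
quantity and is not offered.  Replicate r uses a dedicated generator stream
spawned from (seed, r), so runs are reproducible and parallelizable.

The density of |z| is fitted with D(z) = 2·S_ν,σ(z) — the factor 2 folds the
symmetric non-standardized Student's t onto z ≥ 0 while keeping (ν, σ) their
symmetric-distribution meaning — by minimizing the nominal
χ² = Σ (B_i − D(z_i))² / u_Bi² over bins with u_Bi > 0, at bin midpoints.
The (ν, σ) surface is banana-shaped, so the optimizer works in log
parameters within ν ∈ [0.1, 1000], σ ∈ (0, 100], restarts from three
perturbed initial points and keeps the best χ².  Bins empty in all
replicates are excluded; bins with content but zero bootstrap uncertainty
receive the Poisson-style floor B_i/√(weight sum).

Reported parameter uncertainties are *not* the naive (JᵀJ)⁻¹ errors of that
diagonal χ²: histogram bins are strongly correlated (a single measurement
enters many pairs, and the quantity bootstrap moves many bins together), and
the naive errors undercover by roughly a factor of 2.5.  The fit therefore
propagates the full bootstrap bin covariance through a sandwich estimate at
the optimum.  For histograms of large plain samples the multinomial bin
covariance plays the same role.  With these errors, three-sigma recovery of
(ν, σ) on synthetic data at study scale holds for about 95% of seeds; the
residual misses are genuine heavy-tail behavior — a dataset that happens to
draw few tail events reports both a small u_ν and a high-biased ν.

The nominal χ²/dof is not expected to follow an exact χ² law (correlated,
non-Gaussian bins).  Its spread is calibrated by simulating full datasets
(300 quantities, individual-error ν_x cycling through 1.5, 1.8, 2.4, 2.8 —
values whose pair-level fits land at the ν ≈ 1.6–3.3 range seen across
fields), fitting each, and reporting the fractions with χ²/dof ≤ 0.6 and
≥ 1.9; these come out near 16% and 2%.

## Reference distributions

Exceedance tables use two-sided P(|Z| > z) for Normal, Student's t and
Cauchy, and the one-sided tail convention exp(−z/σ) for the exponential row
(the convention that reproduces the standard printed exponential entries).
z₀.₉₅ solves ccdf(z) = 0.05 by bracketing root-finding to 10⁻¹⁰ relative
tolerance.  The standard two-sided Cauchy 95% point is 12.706; some
published tables print 12.8 for this entry, a last-digit convention this
package does not reproduce.

## Deconvolution to individual errors

Differences of t variates are not exactly t-distributed (outside the Cauchy
and Normal limits), so individual-error parameters are recovered by
simulation: artificial measurements u_i·σ_x·T(ν_x) are built on the real
template of reported uncertainties (true values set to 0 — z is location
invariant), paired and weighted exactly like the data, and (ν_x, σ_x)
adjusted to minimize the χ²-style distance to the observed histogram in its
bins.  One frozen set of uniform draws is pushed through the t quantile at
every candidate ν_x (common random numbers), making the surface smooth for
a coarse log-grid scan refined by Nelder–Mead.  Simulation size is at least
20 simulated pairs per observed pair, capped at 10⁶.  The result is flagged
non-converged when the optimum sticks to the search boundary or the best
match remains grossly incompatible (score per bin > 25).  Recovered ν_x is
below the pair-level ν: individual errors are slightly more Cauchy-like
than pair differences.

## Medical two-arm conversion

Ratio-style binomial endpoints are converted to differences of proportions,
which are Normal in the limit n, np, n(1−p) ≫ 1 (a warn-only check).  Arm
uncertainties are central exact (Clopper–Pearson) 68.3% intervals —
well-defined at k = 0 and k = n — and the difference's asymmetric sides
combine the facing interval half-widths in quadrature.  Exact central
intervals are conservative: their coverage at the 68.3% level is within
3 points of nominal only once np is large enough that discreteness does not
dominate (no exact method does better at, say, n = 50, p = 0.05, where any
interval containing the few probable k values covers ≈ 82%).

## Trends

Relative uncertainty is u/|x| (records with x = 0 are counted and
excluded), histogrammed in log₁₀.  The newer/older relative-uncertainty
ratio of each dated pair, medianed in 5-year publication-gap bins, yields a
halving time from a log-linear fit; ties in year define the ratio as 1.
Improvement factors are u_best_previous/u_new in publication order.  The
median z per gap bin diagnoses bandwagon correlation: independent synthetic
data give a flat trend, while a shared AR(1) drift of contemporaneous
measurements makes short-gap pairs agree better and the median z rise with
gap.  All medians are pair-weighted, ties broken towards the lower value.

## Bound simulation

Hard limits on allowed values (fractions in [0, 1]) leave less room for
large z and so suppress tails.  The effect is measured by simulating
datasets from a baseline (ν_x, σ_x) around each quantity's weighted mean,
with and without truncation to the bounds — truncation by rejection
redrawing, not clipping, which would pile point masses on the bounds — and
refitting both.  Truncation *raises* the naive fitted ν, so the reported
correction delta_nu = nu_unbounded − nu_bounded is never positive beyond
Monte-Carlo noise.  The size of the correction depends strongly on where
truncation bites relative to the fitted z window: bounds at ±10u are
negligible only for light tails (at ν_x ≈ 2.8 they would shift ν by order
1), while the realistic medical case — differences bounded by [−1, 1] with
uncertainties putting the bounds 8–30σ away — shifts ν by a few hundredths
over the z ≤ 10 window in which exceedance results are conventionally
presented.  That window is used for the medical bound check; over the full
z ≤ 20 fitting range the same truncation is several times larger, because
it acts mostly beyond z ≈ 10.

## Unfound-systematics model

A normally distributed systematic of true size t, checked against reported
uncertainty u = t_lower by N_m effective independent consistency checks,
escapes detection when its consistency χ² (which scales as (t/u)²) stays
below a threshold χ²_max ~ N_m − 1.  With a scale-invariant prior
P₀(t) ∝ t^−α, the surviving sizes follow

    f(t) = t^−α · F_χ²[N_m−1](χ²_max · (t_lower/t)²),  t ≥ t_lower,

and the observed error is the scale mixture P(x) = ∫ f(t) N(x; 0, t) dt
(optionally convolved with a Normal(0, t_lower) core; off by default, so the
mixture describes the systematic contribution alone).  The integral is
evaluated by quadrature on a log-t grid (4000 points, truncation at
10⁶·t_lower).  The mixture's far tail is the power law x^−(α+N_m−1) exactly
— the small-argument χ²-CDF contributes t^−(N_m−1) to f — while a
least-squares t-fit over z ∈ [0, 10] lands near ν_pred = N_m − 1 + α (e.g.
ν_fit ≈ 3.2 at N_m = 3, α = 1).  The two notions of "order" (fit over the
data range vs asymptotic exponent) differ by about 1 and both are reported;
they are not asserted equal.  Without censoring, an α ≤ 1 prior is not
normalizable and the fit degenerates to the heavy boundary.

## Synthetic data

The generator emulates the structure of the real compilations: quantities
with 5 + geometric(mean 8) measurements (mean ≈ 13, matching the ≈ 41000
measurements / 3200 quantities of the compiled datasets, with a long tail
of much-measured quantities); reported uncertainties lognormal around a 5%
relative scale, halving every 15 years of publication date; individual
errors u·σ_x·T(ν_x), defaults ν_x = 2, σ_x = 1 (σ scales the t like the
non-standardized σ: HWHM in the Cauchy limit); 5% of records asymmetric
with sides differing by up to 50%; options for lognormal mis-scaling of
reported uncertainties, an AR(1) bandwagon drift in publication order,
bounded fraction-valued quantities (rejection-sampled into [0, 1]) and a
two-arm binomial mode (arm sizes lognormal around 100, control probability
around 0.16, per-quantity effect plus heavy-tailed study-level bias).  All
latent draws are returned in a truth record.

What it does *not* emulate: real selection and publication bias, genuine
inter-record correlations (shared apparatus, theory or authors), non-t
error shapes, and curated quantity-specific bounds.  Passing recovery tests
therefore demonstrates that the pipeline measures what the model generates
at realistic scale — not that any particular real dataset has those
parameters.

The additive structure "binomial counting noise + study bias" in medical
mode cannot reproduce arbitrarily heavy pair tails: a bias of scale
comparable to the counting noise leaves a light-tailed core fit.  The
closest emulation of published clinical comparisons uses a small-core,
near-Cauchy bias (t(1.5) at 0.7 of the counting uncertainty), giving pair
σ ≈ 1.1–1.2 and P(z > 5) ≈ 1–1.5%.

## Problem sizes and numerical defaults

Validation studies run at: 300 quantities per dataset (references at 4000),
1000 bootstrap replicates, 400 calibration replicates, 100 recovery seeds
(25 per parameter setting), 50-dataset bootstrap/ensemble comparison, and
10⁵-pair convention checks.  Optimizer settings: trf least squares in log
parameters, 4 starts, max 400 evaluations; deconvolution grid 12×10 in
log(ν_x)×log(σ_x).  Degenerate inputs (all-equal values, single populated
bin, σ_x = 0) are rejected with explicit errors rather than fitted.
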