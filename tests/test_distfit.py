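"""Student's-t density, reference CCDFs and weighted histogram fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special, stats

from heavytails import (
    ReferenceDistribution,
    ccdf,
    fit_t,
    histogram_of_samples,
    p_normal_of,
    t_pdf,
    z95,
)
from heavytails.distfit import folded_pdf
from heavytails.pairs import WeightedHistogram, default_bin_edges


def t_pdf_oracle(z, nu, sigma):
    """High-precision log-gamma evaluation of the (nu, sigma) t density."""
    lg = (special.gammaln((nu + 1) / 2) - special.gammaln(nu / 2)
          - 0.5 * math.log(nu * math.pi) - math.log(sigma))
    return math.exp(lg) * (1 + (z / sigma) ** 2 / nu) ** (-(nu + 1) / 2)


class TestTPdf:
    def test_cauchy_mode(self):
        assert t_pdf(0.0, 1.0, 1.0) == pytest.approx(1 / math.pi, rel=1e-12)

    def test_normal_limit(self):
        assert t_pdf(0.0, 1e6, 2.0) == pytest.approx(
            1 / (2.0 * math.sqrt(2 * math.pi)), rel=1e-3)

    def test_power_law_tail_ratio(self):
        nu, z = 2.5, 4000.0
        ratio = t_pdf(2 * z, nu, 1.0) / t_pdf(z, nu, 1.0)
        assert ratio == pytest.approx(2.0 ** (-(nu + 1)), rel=1e-3)

    @given(st.floats(0.2, 50), st.floats(0.1, 10), st.floats(-30, 30))
    def test_matches_log_gamma_oracle(self, nu, sigma, z):
        assert t_pdf(z, nu, sigma) == pytest.approx(
            t_pdf_oracle(z, nu, sigma), rel=1e-12)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            t_pdf(0.0, -1.0, 1.0)


# every printed entry of the theoretical exceedance table, to its printed
# precision: P(|Z| > z) at z = 1, 2, 3, 5, 10, then z95 and p_Normal(z95)
TABLE1 = {
    "normal": (ReferenceDistribution("normal"),
               [0.32, 0.046, 0.0027, 5.7e-7, 1.5e-23], 1.96, 5e-2),
    "t10": (ReferenceDistribution("student_t", nu=10),
            [0.34, 0.073, 0.013, 5.4e-4, 1.6e-6], 2.23, 2.6e-2),
    "exponential": (ReferenceDistribution("exponential"),
                    [0.37, 0.14, 0.050, 0.007, 4.5e-5], 3.0, 2.7e-3),
    "t2": (ReferenceDistribution("student_t", nu=2),
           [0.42, 0.18, 0.095, 0.038, 0.010], 4.3, 2e-5),
    "cauchy": (ReferenceDistribution("cauchy"),
               [0.50, 0.30, 0.20, 0.13, 0.063], 12.7, 5e-37),
}


def printed(x, ref):
    """Round x to the precision ref is printed with (half-unit last digit)."""
    from decimal import Decimal

    d = Decimal(str(ref))
    quant = 10.0 ** (d.adjusted() - len(d.as_tuple().digits) + 1)
    return round(x / quant) * quant


class TestReferenceDistributions:
    @pytest.mark.parametrize("name", TABLE1)
    def test_exceedance_table_to_printed_precision(self, name):
        dist, exceeds, zq, p95 = TABLE1[name]
        for z, ref in zip((1, 2, 3, 5, 10), exceeds):
            assert printed(ccdf(dist, float(z)), ref) == pytest.approx(ref)
        assert printed(z95(dist), zq) == pytest.approx(zq)
        assert printed(p_normal_of(z95(dist)), p95) == pytest.approx(p95)

    def test_cauchy_exact_values(self):
        c = ReferenceDistribution("cauchy")
        assert ccdf(c, 1.0) == pytest.approx(0.5, abs=1e-12)
        # the standard two-sided Cauchy 95% point; some tables print 12.8
        assert z95(c) == pytest.approx(12.7062047, abs=1e-5)

    def test_exponential_z95_closed_form(self):
        assert z95(ReferenceDistribution("exponential")) == pytest.approx(
            -math.log(0.05), rel=1e-10)

    @pytest.mark.parametrize("family,kw", [
        ("normal", {}), ("student_t", {"nu": 3.0}), ("cauchy", {}),
        ("exponential", {})])
    def test_ccdf_decreasing_and_z95_round_trip(self, family, kw):
        dist = ReferenceDistribution(family, sigma=1.3, **kw)
        zs = np.linspace(0, 20, 200)
        vals = ccdf(dist, zs)
        assert np.all(np.diff(vals) < 0)
        assert ccdf(dist, z95(dist)) == pytest.approx(0.05, abs=1e-8)
        assert ccdf(dist, 0.0) == pytest.approx(1.0)

    def test_p_normal_examples(self):
        assert p_normal_of(0.0) == 1.0
        assert printed(p_normal_of(5.0), 5.7e-7) == pytest.approx(5.7e-7)

    def test_nu_required_iff_student(self):
        with pytest.raises(ValueError):
            ReferenceDistribution("normal", nu=3.0)
        with pytest.raises(ValueError):
            ReferenceDistribution("student_t")


class TestFitT:
    def test_self_consistency_exact_tabulation(self):
        nu0, sigma0 = 2.4, 1.1
        edges = default_bin_edges()
        mids = 0.5 * (edges[:-1] + edges[1:])
        dens = folded_pdf(mids, nu0, sigma0)
        hist = WeightedHistogram(
            bin_edges=edges, densities=dens,
            uncertainties=np.full_like(dens, 1e-6),
            total_weight=1.0, counts=np.ones_like(dens))
        fit = fit_t(hist)
        assert fit.converged
        assert fit.nu == pytest.approx(nu0, rel=1e-3)
        assert fit.sigma == pytest.approx(sigma0, rel=1e-3)

    def test_cauchy_pairs_quadrature_combination(self, rng):
        # differences of unit Cauchy errors, divided by the quadrature
        # combination sqrt(2), are Cauchy with width sqrt(2)
        T = stats.cauchy.rvs(size=(2, 100_000), random_state=rng)
        z = np.abs(T[0] - T[1]) / math.sqrt(2)
        fit = fit_t(histogram_of_samples(z))
        assert fit.nu == pytest.approx(1.0, abs=0.15)
        assert fit.sigma == pytest.approx(math.sqrt(2), abs=0.1)

    def test_normal_sample_hits_large_nu_degeneracy(self, rng):
        z = np.abs(rng.standard_normal(100_000))
        fit = fit_t(histogram_of_samples(z))
        assert 1.0 / fit.nu == pytest.approx(0.0, abs=1 / 50)
        assert fit.sigma == pytest.approx(1.0, abs=0.03)

    def test_needs_three_usable_bins(self):
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        hist = WeightedHistogram(edges, np.ones(3) / 3, np.zeros(3), 1.0,
                                 counts=np.ones(3))
        with pytest.raises(ValueError):
            fit_t(hist)

    def test_parameter_recovery_direct_samples(self):
        """10^5 z draws straight from heavy-tailed t targets: over the
        (nu, sigma) grid the fit lands within 3 reported uncertainties in
        at least 95% of replicates (multinomial bin covariance makes the
        reported uncertainties honest)."""
        ok = n = 0
        for nu0 in (1.6, 2.0, 2.75, 3.3):
            for sigma0 in (0.9, 1.05, 1.6):
                for s in range(6):
                    rng = np.random.default_rng(hash((nu0, sigma0, s)) % 2**31)
                    z = np.abs(stats.t.rvs(nu0, scale=sigma0, size=100_000,
                                           random_state=rng))
                    fit = fit_t(histogram_of_samples(z))
                    assert fit.converged
                    n += 1
                    ok += fit.within(nu0, sigma0, 3.0)
        assert ok / n >= 0.95
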