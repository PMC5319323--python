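"""Normalized differences, weighting schemes and weighted histograms."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heavytails import (
    QuantitySeries,
    build_histogram,
    empirical_ccdf,
    enumerate_pairs,
    h_statistic,
    i_squared,
    weighted_mean,
    weighted_quantile,
    z_covariance,
    z_linear,
    z_quadrature,
)
from heavytails.pairs import PairStatistic, histogram_from_arrays

from conftest import record

finite_vals = st.floats(-1e3, 1e3)
pos_u = st.floats(0.01, 1e2)


def rec_strategy():
    return st.builds(record, finite_vals, pos_u, pos_u)


class TestZQuadrature:
    def test_worked_example(self, worked_example_records):
        x1, x2, x3 = worked_example_records
        # x1 < x2: the sides facing each other are +3 (x1) and -4 (x2)
        assert z_quadrature(x1, x2) == pytest.approx((100 - 80) / 5.0)
        assert z_quadrature(x2, x3) == pytest.approx((126 - 100) / 13.0)

    def test_identical_values_zero(self):
        assert z_quadrature(record(5, 1), record(5, 2)) == 0.0

    @given(rec_strategy(), rec_strategy())
    def test_symmetry(self, a, b):
        assert z_quadrature(a, b) == pytest.approx(z_quadrature(b, a))

    @given(rec_strategy(), rec_strategy(), st.floats(0.01, 100))
    def test_scale_invariance(self, a, b, c):
        from dataclasses import replace
        scale = lambda r: replace(r, value=c * r.value, u_plus=c * r.u_plus,
                                  u_minus=c * r.u_minus)
        assert z_quadrature(scale(a), scale(b)) == pytest.approx(
            z_quadrature(a, b), rel=1e-9)


class TestZVariants:
    def test_covariance_zero_reduces_to_quadrature(self, worked_example_records):
        x1, x2, _ = worked_example_records
        assert z_covariance(x1, x2, 0.0) == pytest.approx(z_quadrature(x1, x2))

    def test_perfect_anticorrelation_reduces_by_sqrt2(self):
        a, b = record(0, 2), record(3, 2)
        assert z_covariance(a, b, -4.0) == pytest.approx(
            z_quadrature(a, b) / math.sqrt(2))

    def test_full_positive_correlation_rejected(self):
        with pytest.raises(ValueError):
            z_covariance(record(0, 2), record(3, 2), +4.0)

    def test_linear_equals_quadrature_over_sqrt2_at_equal_u(self):
        a, b = record(0, 1.5), record(4, 1.5)
        assert z_linear(a, b) == pytest.approx(
            z_quadrature(a, b) / math.sqrt(2))

    def test_linear_simple(self):
        assert z_linear(record(0, 1), record(2, 1)) == pytest.approx(1.0)
        assert z_linear(record(7, 1), record(7, 3)) == 0.0

    @given(rec_strategy(), rec_strategy())
    def test_linear_never_exceeds_quadrature(self, a, b):
        assert z_linear(a, b) <= z_quadrature(a, b) + 1e-12


class TestWeightedMeanAndH:
    def test_equal_uncertainties_arithmetic_mean(self):
        s = QuantitySeries("Q", tuple(record(v, 2.0, qid="Q") for v in (1, 2, 3, 4)))
        x, u = weighted_mean(s)
        assert x == pytest.approx(2.5)
        assert u == pytest.approx(2.0 / 2.0)  # u/sqrt(N)

    def test_single_record(self):
        x, u = weighted_mean(QuantitySeries("Q", (record(3.0, 0.4, qid="Q"),)))
        assert (x, u) == (3.0, pytest.approx(0.4))

    def test_direct_formula(self):
        # (0 +- 1, 3 +- 2): weights 1, 1/4 -> mean 0.6, u = 2/sqrt(5)
        s = QuantitySeries("Q", (record(0, 1, qid="Q"), record(3, 2, qid="Q")))
        x, u = weighted_mean(s)
        assert x == pytest.approx(0.6)
        assert u == pytest.approx(2 / math.sqrt(5))

    def test_h_from_formula(self):
        s = QuantitySeries("Q", (record(0, 1, qid="Q"), record(3, 2, qid="Q")))
        h = h_statistic(s.measurements[0], s)
        assert h.h == pytest.approx(0.6 / math.hypot(1.0, 2 / math.sqrt(5)))

    def test_h_identical_records_zero(self):
        s = QuantitySeries("Q", tuple(record(2, 1, qid="Q") for _ in range(4)))
        assert all(h_statistic(m, s).h == 0.0 for m in s.measurements)

    def test_h_two_equal_u_records_symmetric(self):
        s = QuantitySeries("Q", (record(0, 1, qid="Q"), record(2, 1, qid="Q")))
        h1, h2 = (h_statistic(m, s).h for m in s.measurements)
        assert h1 == pytest.approx(h2)


class TestEnumeratePairs:
    def test_m_weighting_ten_measurements(self):
        s = QuantitySeries("Q", tuple(
            record(float(i), 1.0, qid="Q") for i in range(10)))
        pairs = enumerate_pairs(s, scheme="M")
        assert len(pairs) == 45
        assert all(p.weight == pytest.approx(10 / 45) for p in pairs)

    @pytest.mark.parametrize("scheme, per_pair, total", [
        ("Q", 1 / 10, 1.0), ("M", 5 / 10, 5.0), ("P", 1.0, 10.0)])
    def test_scheme_totals_n5(self, scheme, per_pair, total):
        s = QuantitySeries("Q", tuple(
            record(float(i), 1.0, qid="Q") for i in range(5)))
        pairs = enumerate_pairs(s, scheme=scheme)
        assert len(pairs) == 10
        assert pairs[0].weight == pytest.approx(per_pair)
        assert sum(p.weight for p in pairs) == pytest.approx(total)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_brute_force_oracle(self, n):
        recs = tuple(record(float(i * i), 1.0 + 0.1 * i, qid="Q",
                            record_id=f"r{i}") for i in range(n))
        s = QuantitySeries("Q", recs)
        pairs = enumerate_pairs(s, scheme="M")
        expected = {(a.record_id, b.record_id):
                    z_quadrature(a, b) for a, b in itertools.combinations(recs, 2)}
        assert len(pairs) == len(expected) == n * (n - 1) // 2
        for p in pairs:
            assert p.z == pytest.approx(expected[(p.id_a, p.id_b)])
            assert p.weight == pytest.approx(n / len(expected))

    def test_year_gap_and_ratio(self):
        a = record(10.0, 1.0, qid="Q", year=2000.0, record_id="a")
        b = record(12.0, 0.6, qid="Q", year=2010.0, record_id="b")
        (p,) = enumerate_pairs(QuantitySeries("Q", (a, b)))
        assert p.year_gap == 10.0
        assert p.rel_unc_ratio == pytest.approx((0.6 / 12.0) / (1.0 / 10.0))

    def test_zero_value_record_has_no_ratio(self):
        a = record(0.0, 1.0, qid="Q", year=2000.0)
        b = record(1.0, 1.0, qid="Q", year=2005.0)
        (p,) = enumerate_pairs(QuantitySeries("Q", (a, b)))
        assert p.year_gap == 5.0 and p.rel_unc_ratio is None


class TestHistogram:
    def test_single_bin_density(self):
        h = histogram_from_arrays(np.array([0.5, 0.6]), np.ones(2),
                                  np.array([0.0, 1.0, 2.0]))
        assert h.densities[0] == pytest.approx(1.0)
        assert h.total_probability == pytest.approx(1.0)

    def test_two_bins_split(self):
        h = histogram_from_arrays(np.array([0.5, 1.5]), np.ones(2),
                                  np.array([0.0, 1.0, 2.0]))
        assert h.densities == pytest.approx([0.5, 0.5])

    def test_weight_rescaling_invariance(self):
        z = np.array([0.3, 1.2, 2.7, 0.8])
        w = np.array([1.0, 2.0, 0.5, 1.5])
        h1 = histogram_from_arrays(z, w)
        h2 = histogram_from_arrays(z, 7.0 * w)
        assert h1.densities == pytest.approx(h2.densities)

    def test_overflow_included_in_total(self):
        h = histogram_from_arrays(np.array([0.5, 50.0]), np.ones(2))
        assert h.overflow_mass == pytest.approx(0.5)
        assert h.total_probability == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([])

    def test_build_from_pairs(self, simple_series):
        pairs = enumerate_pairs(simple_series)
        h = build_histogram(pairs)
        assert h.total_probability == pytest.approx(1.0, abs=1e-9)
        assert h.total_weight == pytest.approx(len(simple_series))


class TestEmpiricalCCDF:
    def test_thresholds(self):
        pairs = [PairStatistic(z=2.0, weight=1.0)]
        exceed, z95 = empirical_ccdf(pairs, [0.0, 1.0, 5.0])
        assert exceed == pytest.approx([1.0, 1.0, 0.0])
        assert z95 == 2.0

    def test_monotone_nonincreasing(self, simple_series):
        pairs = enumerate_pairs(simple_series)
        exceed, _ = empirical_ccdf(pairs, [0.0, 0.5, 1.0, 2.0])
        assert np.all(np.diff(exceed) <= 1e-12)


class TestWeightedQuantile:
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_unit_weights_match_sorted_pick(self, vals):
        v = np.array(vals)
        w = np.ones_like(v)
        med = weighted_quantile(v, w, 0.5)
        s = np.sort(v)
        cum = np.arange(1, len(s) + 1)
        assert med == s[np.searchsorted(cum, 0.5 * len(s), side="left")]


class TestISquared:
    def test_consistent_data_zero(self):
        s = QuantitySeries("Q", tuple(record(5.0, 1.0, qid="Q") for _ in range(4)))
        assert i_squared(s) == 0.0

    def test_known_chi2_values(self):
        # chi2_c = 2(N-1) -> I^2 = 0.5; construct (0+-1, 2+-1): chi2=2, N=2
        s = QuantitySeries("Q", (record(0, 1, qid="Q"), record(2, 1, qid="Q")))
        assert i_squared(s) == pytest.approx(0.5)
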