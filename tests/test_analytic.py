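"""Closed-form results: rate balance, parameter inversions, stationary laws."""

import math

import numpy as np
import pytest

from antenna import (
    AntennaParameters,
    FAST_SWITCHING,
    YEAST,
    YEAST_EXACT_D,
    average_polymerization_rate,
    binding_rate,
    distribution_moments,
    geometric_characteristic_length,
    mean_length_balance,
    solve_for_d,
    solve_for_w,
    stationary_distribution_closed_form,
    stationary_distribution_recursive,
    tv_distance,
)
from antenna.distributions import LengthDistribution, Provenance


class TestBindingRate:
    def test_zero_length_captures_nothing(self):
        assert binding_rate(0, YEAST) == 0.0

    def test_yeast_cable_delivery_rate(self):
        # a 5 um cable (1850 subunits) at w = 0.004 delivers inhibitor at 7.4/s
        assert binding_rate(1850, YEAST) == pytest.approx(7.4)

    def test_linear_in_length(self):
        assert binding_rate(2 * 617, YEAST) == 2 * binding_rate(617, YEAST)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            binding_rate(-1, YEAST)


class TestAveragePolymerizationRate:
    def test_uninhibited_at_zero_length(self):
        assert average_polymerization_rate(0, YEAST) == YEAST.r

    def test_half_rate_at_kon_koff_symmetry_point(self):
        l_half = YEAST.k_off / YEAST.w
        assert average_polymerization_rate(l_half, YEAST) == pytest.approx(
            YEAST.r / 2
        )

    def test_yeast_mean_length_value(self):
        # at the observed 5 um mean, growth has slowed to ~44 subunits/s,
        # the same value the mean-length inversion recovers for d
        assert average_polymerization_rate(1850, YEAST) == pytest.approx(
            370 / 8.4
        )

    def test_strictly_decreasing_in_length(self):
        grid = np.arange(0, 5000, 37)
        rates = [average_polymerization_rate(l, YEAST) for l in grid]
        assert np.all(np.diff(rates) < 0)

    def test_permanently_inhibited_without_unbinding(self):
        params = YEAST.with_(k_off=0.0)
        assert average_polymerization_rate(100, params) == 0.0


class TestMeanLengthBalance:
    def test_balance_at_zero_when_rates_equal(self):
        assert mean_length_balance(AntennaParameters(5, 5, 0.1, 1)) == 0.0

    def test_yeast_inversion_round_trip(self):
        assert mean_length_balance(YEAST_EXACT_D) == pytest.approx(1850.0)

    def test_doubling_w_halves_the_mean(self):
        assert mean_length_balance(YEAST.with_(w=0.008)) == pytest.approx(
            mean_length_balance(YEAST) / 2
        )

    def test_no_growth_returns_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert mean_length_balance(AntennaParameters(2, 5, 0.1, 1)) == 0.0
        assert "no net growth" in caplog.text.lower() or caplog.records


class TestInversions:
    def test_solve_for_d_recovers_depolymerization_rate(self):
        d = solve_for_d(370, 1, 0.004, 1850)
        assert d == pytest.approx(370 / 8.4)  # 44.05 subunits/s ~ 0.12 um/s

    def test_d_approaches_r_for_short_targets(self):
        assert solve_for_d(370, 1, 0.004, 1e-9) == pytest.approx(370, rel=1e-9)

    def test_mean_balance_inverts_solve_for_d(self):
        d = solve_for_d(370, 1, 0.004, 1234.5)
        assert mean_length_balance(YEAST.with_(d=d)) == pytest.approx(1234.5)

    @pytest.mark.parametrize(
        "k_off,expected", [(50.0, 0.1952), (0.5, 0.001952)]
    )
    def test_solve_for_w_fixed_mean_settings(self, k_off, expected):
        # the weak/strong-affinity pairs that hold the mean at 5 um
        assert solve_for_w(370, 45, k_off, 1850) == pytest.approx(
            expected, rel=1e-3
        )

    def test_w_scales_with_k_off_at_fixed_mean(self):
        assert solve_for_w(370, 45, 7 * 2.0, 1850) == pytest.approx(
            7 * solve_for_w(370, 45, 2.0, 1850)
        )

    def test_solve_for_w_requires_net_growth(self):
        with pytest.raises(ValueError):
            solve_for_w(45, 45, 1, 1850)


class TestStationaryRecursion:
    def test_normalized(self):
        dist = stationary_distribution_recursive(YEAST)
        assert dist.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.provenance is Provenance.ANALYTIC_RECURSION

    def test_geometric_limit_without_feedback(self):
        # w = 0, r < d: plain birth-death with geometric stationary law
        params = AntennaParameters(r=1.0, d=2.0, w=0.0, k_off=1.0)
        dist = stationary_distribution_recursive(params)
        expected = (1 - 0.5) * 0.5 ** np.arange(dist.p.size)
        np.testing.assert_allclose(dist.p, expected, rtol=1e-9, atol=1e-300)
        assert geometric_characteristic_length(params) == pytest.approx(
            1 / math.log(2)
        )
        mean, _, _ = distribution_moments(dist)
        assert mean == pytest.approx(0.5 / (1 - 0.5), rel=1e-9)

    def test_time_unit_invariance(self):
        scaled = AntennaParameters(
            r=YEAST.r * 7.3, d=YEAST.d * 7.3, w=YEAST.w * 7.3,
            k_off=YEAST.k_off * 7.3,
        )
        a = stationary_distribution_recursive(YEAST)
        b = stationary_distribution_recursive(scaled)
        assert tv_distance(a, b) < 1e-12

    def test_identical_across_fixed_mean_pairs(self):
        # the detailed-balance law depends on (k_off, w) only through their
        # ratio, so fixed-mean pairs share one recursion distribution; the
        # variance reduction at large k_off is a slow-switching effect that
        # only the exact solvers resolve
        a = stationary_distribution_recursive(YEAST)
        b = stationary_distribution_recursive(YEAST.with_(k_off=10.0, w=0.04))
        assert tv_distance(a, b) < 1e-12

    def test_unbounded_growth_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution_recursive(
                AntennaParameters(r=2.0, d=1.0, w=0.0, k_off=1.0)
            )

    def test_tail_mass_below_tolerance(self):
        dist = stationary_distribution_recursive(YEAST)
        assert dist.p[-1] < 1e-14 * dist.p.max()


class TestClosedForm:
    def test_matches_recursion_pointwise(self):
        rec = stationary_distribution_recursive(FAST_SWITCHING)
        cf = stationary_distribution_closed_form(FAST_SWITCHING, l_max=rec.l_max)
        mask = rec.p > 1e-300
        ratio = cf.p[mask][3:] / rec.p[mask][3:]
        np.testing.assert_allclose(ratio, 1.0, rtol=1e-6)

    def test_detailed_balance_ratio(self):
        cf = stationary_distribution_closed_form(YEAST, l_max=4000)
        l = np.arange(600, 3000)
        ratio = cf.p[l + 1] / cf.p[l]
        rbar = np.array([average_polymerization_rate(x, YEAST) for x in l])
        np.testing.assert_allclose(ratio, rbar / YEAST.d, rtol=1e-10)

    def test_normalized_over_support(self):
        cf = stationary_distribution_closed_form(FAST_SWITCHING)
        assert cf.p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_requires_full_inhibition(self):
        with pytest.raises(ValueError):
            stationary_distribution_closed_form(YEAST.with_(r_off=1.0))


class TestMoments:
    def test_point_mass(self):
        p = np.zeros(11)
        p[7] = 1.0
        dist = LengthDistribution(p, Provenance.EMPIRICAL)
        assert distribution_moments(dist) == (7.0, 0.0, 0.0)

    def test_cv2_undefined_at_zero_mean(self):
        p = np.zeros(3)
        p[0] = 1.0
        dist = LengthDistribution(p, Provenance.EMPIRICAL)
        assert math.isnan(dist.cv2())
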