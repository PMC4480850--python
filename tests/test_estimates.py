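"""In-vivo parameter estimates and alternative length-control calculations."""


import pytest

from antenna.estimates import (
    FinitePoolParameters,
    MotorTransportObservables,
    SeveringParameters,
    actin_count_from_concentration,
    estimate_w,
    finite_pool_mean,
    micron_subunit_conversions,
    motor_density_profile,
    parameter_provenance,
    round_to_sig_figs,
    severing_depolymerization_rate,
    severing_steady_length,
    total_motors,
)
from antenna.params import subunits_to_microns

NOMINAL_MOTORS = MotorTransportObservables(
    n_tot=5, cable_length_um=5.0, myosin_speed_um_s=3.5
)


class TestMotorTransport:
    def test_density_vanishes_at_cable_start(self):
        assert motor_density_profile(0, kon0=0.004, v=1296.3) == 0.0

    def test_density_linear_in_position(self):
        a = motor_density_profile(500, 0.004, 1296.3)
        assert motor_density_profile(1000, 0.004, 1296.3) == pytest.approx(2 * a)

    def test_total_motors_equals_brute_force_sum(self):
        kon0, v = 0.004, 1296.3
        brute = sum(motor_density_profile(x, kon0, v) for x in range(1, 1001))
        assert total_motors(1000, kon0, v) == pytest.approx(brute)

    def test_total_motors_edge_cases(self):
        assert total_motors(0, 0.004, 100.0) == 0.0
        assert total_motors(1, 0.004, 100.0) == pytest.approx(0.004 / 100.0)

    def test_w_estimate_from_observed_motor_count(self):
        # 5 complexes on a 5 um cable with 3.5 um/s motors -> w = 0.004
        # to one significant figure
        w = estimate_w(NOMINAL_MOTORS)
        assert w == pytest.approx(0.00378, rel=1e-2)
        assert round_to_sig_figs(w, 1) == 0.004

    def test_w_linear_in_motor_count(self):
        doubled = MotorTransportObservables(
            n_tot=10, cable_length_um=5.0, myosin_speed_um_s=3.5
        )
        assert estimate_w(doubled) == pytest.approx(2 * estimate_w(NOMINAL_MOTORS))

    def test_no_motors_no_delivery(self):
        empty = MotorTransportObservables(
            n_tot=0, cable_length_um=5.0, myosin_speed_um_s=3.5
        )
        assert estimate_w(empty) == 0.0

    def test_slow_motors_warned(self, caplog):
        with caplog.at_level("WARNING"):
            MotorTransportObservables(
                n_tot=5, cable_length_um=5.0, myosin_speed_um_s=0.5
            )
        assert "speed" in caplog.text


class TestFinitePool:
    NOMINAL = FinitePoolParameters(
        n_actin=3e5, n_cables=10, filaments_per_cable=4,
        r_prime=1.2e-3, d=45.0,
    )

    def test_pool_limited_length_is_18_microns(self):
        mean_sub = finite_pool_mean(self.NOMINAL)
        assert mean_sub == pytest.approx(6562.5)
        assert round(subunits_to_microns(mean_sub)) == 18

    def test_exhausted_pool_gives_zero(self):
        params = FinitePoolParameters(
            n_actin=45 / 1.2e-3, n_cables=10, filaments_per_cable=4,
            r_prime=1.2e-3, d=45.0,
        )
        assert finite_pool_mean(params) == 0.0

    def test_doubling_cable_number_halves_mean(self):
        doubled = FinitePoolParameters(
            n_actin=3e5, n_cables=20, filaments_per_cable=4,
            r_prime=1.2e-3, d=45.0,
        )
        assert finite_pool_mean(doubled) == pytest.approx(
            finite_pool_mean(self.NOMINAL) / 2
        )

    def test_actin_count_from_concentration(self):
        # 10 uM in a 2.5 um-radius sphere: ~3.9e5 molecules (the
        # conventionally quoted 3e5 agrees only to order of magnitude)
        n = actin_count_from_concentration(10e-6, 2.5)
        assert n == pytest.approx(3.94e5, rel=1e-2)

    def test_actin_count_scales_with_volume(self):
        assert actin_count_from_concentration(10e-6, 5.0) == pytest.approx(
            8 * actin_count_from_concentration(10e-6, 2.5)
        )

    def test_actin_count_zero_concentration(self):
        assert actin_count_from_concentration(0.0, 2.5) == 0.0


class TestSevering:
    def test_loss_rate_quadratic_in_length(self):
        assert severing_depolymerization_rate(0.0, 1e-3) == 0.0
        assert severing_depolymerization_rate(10.0, 1e-3) == pytest.approx(
            4 * severing_depolymerization_rate(5.0, 1e-3)
        )

    def test_steady_length_is_45_microns(self):
        length = severing_steady_length(SeveringParameters(1.0, 1e-3))
        assert round(length) == 45

    def test_steady_length_balances_loss_against_growth(self):
        p = SeveringParameters(1.0, 1e-3)
        l_star = severing_steady_length(p)
        assert severing_depolymerization_rate(l_star, p.s_per_um_s) == (
            pytest.approx(p.r_um_s)
        )

    def test_quadrupling_severing_halves_length(self):
        assert severing_steady_length(SeveringParameters(1.0, 4e-3)) == (
            pytest.approx(severing_steady_length(SeveringParameters(1.0, 1e-3)) / 2)
        )


class TestConversions:
    def test_micron_per_second_growth_rate(self):
        assert micron_subunit_conversions(1.0, "um_to_subunits") == 370.0

    def test_five_micron_cable(self):
        assert micron_subunit_conversions(1850.0, "subunits_to_um") == 5.0

    def test_round_trip_identity(self):
        x = micron_subunit_conversions(
            micron_subunit_conversions(7.3, "um_to_subunits"),
            "subunits_to_um",
        )
        assert x == pytest.approx(7.3, rel=1e-15)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            micron_subunit_conversions(1.0, "sideways")


class TestProvenance:
    def test_full_chain_reproduces_parameter_set(self):
        rows = {
            (row["quantity"], row["units"]): row for row in parameter_provenance()
        }
        assert rows[("r", "subunits/s")]["value"] == 370.0
        assert rows[("k_off", "1/s")]["value"] == 1.0
        assert rows[("w", "1/(subunit s)")]["rounded"] == 0.004
        assert rows[("d", "subunits/s")]["value"] == pytest.approx(370 / 8.4)
        assert rows[("d", "um/s")]["rounded"] == 0.12
        assert rows[("finite-pool mean length", "um")]["rounded"] == 18
        assert rows[("severing steady length", "um")]["rounded"] == 45

    def test_pure_function(self):
        assert parameter_provenance() == parameter_provenance()
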