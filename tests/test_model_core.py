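import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import quad

from sulfosim.environment import WeatherRecord
from sulfosim.model_core import (
    ModelParameters,
    PlantState,
    SimulationError,
    biomass_production,
    carb_limited_la_increment,
    fallen_leaf_dw,
    initial_state_from,
    potential_la_increment,
    potential_leaf_area,
    simulate,
    step,
)

HS_SIGMOID = dict(la0=0.016, la_max=0.20, k_half=872.96, n_shape=6.31)


def make_params(**overrides) -> ModelParameters:
    base = dict(
        ds=40.0,
        k=0.75,
        rue=4.59,
        sla=0.028,
        beta_alloc=0.41,
        qs_ini=8.799,
        a_qs=7.540,
        b_qs=0.0033,
        dw_fl_ini=0.0,
        a_ldw_fl=0.0092,
        b_ldw_fl=0.0043,
        alpha_bl=5.11,
        beta_bl=-0.52,
        alpha_rest=1.83,
        beta_rest=-0.004,
        eps_pot=0.8,
        tt_offset=480.0,
        **HS_SIGMOID,
    )
    base.update(overrides)
    p = ModelParameters(**base)
    p.validate()
    return p


class TestPotentialLeafArea:
    def test_origin_returns_initial_area(self):
        p = make_params()
        assert potential_leaf_area(0.0, p) == p.la0

    def test_half_saturation(self):
        p = make_params()
        mid = p.la0 + (p.la_max - p.la0) / 2.0
        assert potential_leaf_area(p.k_half, p) == pytest.approx(mid, rel=1e-12)

    def test_value_matches_scalar_evaluation(self):
        # frozen high-precision evaluation of the sigmoid at tt = 1200
        p = make_params()
        assert potential_leaf_area(1200.0, p) == pytest.approx(
            0.17821614549470027, rel=1e-10
        )

    def test_monotone_and_bounded(self):
        p = make_params()
        tts = np.linspace(0.0, 3000.0, 200)
        values = [potential_leaf_area(t, p) for t in tts]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] < p.la_max


class TestPotentialIncrement:
    def test_zero_dtt_gives_zero(self):
        assert potential_la_increment(500.0, 0.0, make_params()) == 0.0

    def test_telescoping_partition(self):
        """Summed increments over any partition recover the curve difference."""
        p = make_params()
        cuts = np.sort(np.concatenate([[0.0, 1500.0], np.linspace(13, 1400, 37)]))
        total = sum(
            potential_la_increment(a, b - a, p) for a, b in zip(cuts, cuts[1:])
        )
        expected = potential_leaf_area(1500.0, p) - p.la0
        assert total == pytest.approx(expected, rel=1e-9)

    def test_matches_two_evaluations(self):
        p = make_params()
        expected = potential_leaf_area(810.0, p) - potential_leaf_area(800.0, p)
        assert potential_la_increment(800.0, 10.0, p) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected > 0


class TestBiomassProduction:
    def test_zero_par_zero_production(self):
        assert biomass_production(0.0, make_params()) == 0.0

    def test_per_plant_value(self):
        # 1 MJ m^-2 at RUE 4.59 and 40 plants m^-2
        assert biomass_production(1.0, make_params()) == pytest.approx(
            0.11475, rel=1e-12
        )

    def test_canopy_scale_identity(self):
        p = make_params()
        par_abs = 3.7
        assert biomass_production(par_abs, p) * p.ds == pytest.approx(
            p.rue * par_abs, rel=1e-12
        )


class TestCarbonIncrement:
    def test_examples(self):
        p = make_params()
        assert carb_limited_la_increment(0.0, p) == 0.0
        assert carb_limited_la_increment(1.0, p) == pytest.approx(0.01148, rel=1e-12)

    def test_identity_when_unit_coefficients(self):
        p = make_params(beta_alloc=1.0, sla=1.0)
        assert carb_limited_la_increment(0.37, p) == pytest.approx(0.37, rel=1e-12)


class TestFallenLeafDw:
    def test_initial_value(self):
        for provider in ("exp_amplitude", "rate_integral"):
            p = make_params(dw_fl_ini=0.05, leaf_fall_provider=provider)
            assert fallen_leaf_dw(0.0, p) == pytest.approx(0.05, rel=1e-12)

    def test_rate_integral_matches_quadrature(self):
        # frozen value 2.91653 g at tt = 200, cross-checked by integrating
        # the exponential fall rate numerically
        p = make_params(leaf_fall_provider="rate_integral", dw_fl_ini=0.0)
        value = fallen_leaf_dw(200.0, p)
        assert value == pytest.approx(2.91652985630077, rel=1e-10)
        oracle, _ = quad(lambda t: p.a_ldw_fl * math.exp(p.b_ldw_fl * t), 0, 200)
        assert value == pytest.approx(oracle, rel=1e-9)

    def test_rate_integral_linear_limit(self):
        p = make_params(leaf_fall_provider="rate_integral", b_ldw_fl=0.0)
        assert fallen_leaf_dw(100.0, p) == pytest.approx(0.92, rel=1e-12)

    def test_monotone_non_decreasing(self):
        for provider in ("exp_amplitude", "rate_integral"):
            p = make_params(leaf_fall_provider=provider)
            tts = np.linspace(0.0, 800.0, 100)
            values = [fallen_leaf_dw(t, p) for t in tts]
            assert all(b >= a for a, b in zip(values, values[1:]))


class TestStep:
    def hs_initial_state(self, p):
        return initial_state_from(
            p, tdw_ini=0.652, ldw_bl_ini=0.510, qs_bl_ini=7.48, qs_rest_ini=1.32
        )

    def test_dark_day_is_carbon_limited(self):
        p = make_params()
        state = self.hs_initial_state(p)
        _, flux = step(state, WeatherRecord(1, 10.0, 20.0, 0.0), p)
        assert flux.dla_carb == 0.0
        assert flux.dla_eff == 0.0
        assert flux.limiting_factor == "carbon"

    def test_zero_sulfur_offer_is_sulfur_limited(self):
        p = make_params(a_qs=0.0)
        state = self.hs_initial_state(p)
        _, flux = step(state, WeatherRecord(1, 10.0, 20.0, 5.0), p)
        assert flux.dqs_offer == 0.0
        assert flux.dla_s == 0.0
        assert flux.dla_eff == 0.0
        assert flux.limiting_factor == "sulfur"

    def test_single_step_against_hand_computation(self):
        """Every sub-quantity of one update recomputed independently."""
        p = make_params()
        state = self.hs_initial_state(p)
        new, flux = step(state, WeatherRecord(1, 10.0, 20.0, 5.0), p)

        # independent recomputation from the closed-form pieces
        dtt = (10.0 + 20.0) / 2.0 - 5.0
        par_abs = 5.0 * (1.0 - math.exp(-p.k * 0.016 * 40.0))
        d_tdw = 4.59 * par_abs / 40.0

        def sigmoid(tt):
            r = (tt / 872.96) ** 6.31
            return 0.016 + (0.20 - 0.016) * r / (1.0 + r)

        dla_tt = sigmoid(480.0 + dtt) - sigmoid(480.0)
        dla_carb = 0.41 * d_tdw * 0.028
        fall = lambda tt: 0.0092 * (
            math.exp(0.0043 * (tt + 480.0)) - math.exp(0.0043 * 480.0)
        )
        d_ldw_fl = fall(dtt) - fall(0.0)
        dqs_uptake = 7.540 * (math.exp(0.0033 * dtt) - 1.0)
        # mobile pools start empty: offer is uptake only
        dqs_offer = dqs_uptake
        s_crit = 3.0  # 0.51 g is below the 3 g dilution-curve threshold
        dla_s = dqs_offer * 0.028 / s_crit
        dla_eff = min(dla_tt, dla_carb, dla_s)

        assert flux.dtt == pytest.approx(dtt, rel=1e-12)
        assert flux.par_abs == pytest.approx(par_abs, rel=1e-12)
        assert flux.d_tdw == pytest.approx(d_tdw, rel=1e-12)
        assert flux.dla_tt == pytest.approx(dla_tt, rel=1e-10)
        assert flux.dla_carb == pytest.approx(dla_carb, rel=1e-12)
        assert flux.d_ldw_fl == pytest.approx(d_ldw_fl, rel=1e-10)
        assert flux.dqs_uptake == pytest.approx(dqs_uptake, rel=1e-12)
        assert flux.dla_s == pytest.approx(dla_s, rel=1e-12)
        assert flux.dla_eff == pytest.approx(dla_eff, rel=1e-10)
        assert flux.limiting_factor == "temperature"  # dla_tt is smallest here

        # biomass bookkeeping
        assert new.tdw == pytest.approx(0.652 + d_tdw, rel=1e-12)
        assert new.ldw_bl == pytest.approx(
            0.510 + dla_eff / 0.028 - d_ldw_fl, rel=1e-10
        )
        assert new.la_bl == pytest.approx(
            0.016 + dla_eff - d_ldw_fl * 0.028, rel=1e-10
        )
        assert new.dw_rest == pytest.approx(
            0.142 + d_tdw - dla_eff / 0.028, rel=1e-10
        )
        # sulfur: BL demand served first, then rest, remainder is surplus
        bl_req = s_crit * (dla_eff - d_ldw_fl * 0.028) / 0.028
        rest_growth = d_tdw - dla_eff / 0.028
        rest_req = 1.83 * 0.142 ** (-0.004) * rest_growth
        served_bl = min(max(bl_req, 0.0), dqs_offer)
        served_rest = min(rest_req, dqs_offer - served_bl)
        fl_org = 7.48 * d_ldw_fl / 0.510
        assert new.qs_org_bl == pytest.approx(7.48 - fl_org + served_bl, rel=1e-10)
        assert new.qs_org_rest == pytest.approx(1.32 + served_rest, rel=1e-10)
        surplus = dqs_offer - served_bl - served_rest
        assert new.qs_mobile_bl + new.qs_mobile_rest == pytest.approx(
            surplus, abs=1e-12
        )
        assert new.qs_fl == pytest.approx(fl_org, rel=1e-10)

    def test_non_finite_weather_rejected(self):
        p = make_params()
        state = self.hs_initial_state(p)
        with pytest.raises(Exception):
            step(state, WeatherRecord(1, math.inf, math.inf, 5.0), p)


class TestSimulate:
    def test_empty_series_returns_initial_state_only(self):
        p = make_params()
        init = initial_state_from(
            p, tdw_ini=0.652, ldw_bl_ini=0.510, qs_bl_ini=7.48, qs_rest_ini=1.32
        )
        traj = simulate([], init, p)
        assert traj.states() == [init]
        assert traj.final_state == init

    def test_fold_composition(self, hs_config, weather60):
        """simulate(A + B) equals simulate(B) started from simulate(A)'s end."""
        params, init = hs_config
        half_a, half_b = weather60[:30], weather60[30:]
        full = simulate(weather60, init, params)
        first = simulate(half_a, init, params)
        second = simulate(half_b, first.final_state, params)
        assert second.final_state == full.final_state  # bit-identical fold

    def test_deterministic(self, hs_config, weather60):
        params, init = hs_config
        a = simulate(weather60, init, params)
        b = simulate(weather60, init, params)
        assert a.states() == b.states()

    def test_error_carries_day_index(self, hs_config):
        params, init = hs_config
        bad = [WeatherRecord(1, 10.0, 20.0, 5.0)]
        object.__setattr__(bad[0], "par_incident", float("nan"))
        with pytest.raises(SimulationError, match="day 1"):
            simulate(bad, init, params)

    def test_trajectory_frame_shape(self, hs_trajectory):
        frame = hs_trajectory.to_frame()
        assert len(frame) == 61  # 60 days + initial row
        assert frame["tt_cum"].is_monotonic_increasing


class TestConservation:
    def test_dry_weight_closure_every_step(self, hs_trajectory, ls_trajectory):
        for traj in (hs_trajectory, ls_trajectory):
            for state in traj.states():
                total = state.ldw_bl + state.ldw_fl + state.dw_rest
                assert total == pytest.approx(state.tdw, rel=1e-9)

    def test_sulfur_closure_every_step(self, hs_trajectory, ls_trajectory):
        for traj in (hs_trajectory, ls_trajectory):
            s0 = traj.initial_state
            for state in traj.states():
                lhs = state.qs_tot + state.qs_fl
                rhs = s0.qs_tot + s0.qs_fl + state.qs_uptake_cum
                assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_production_sums_to_tdw(self, hs_trajectory):
        s0 = hs_trajectory.initial_state
        total = sum(flux.d_tdw for _, _, flux in hs_trajectory.records)
        assert hs_trajectory.final_state.tdw == pytest.approx(
            s0.tdw + total, rel=1e-9
        )


class TestInitialState:
    def test_rest_is_residual(self, hs_config):
        params, init = hs_config
        assert init.dw_rest == pytest.approx(0.652 - 0.510, rel=1e-12)
        assert init.tdw == pytest.approx(
            init.ldw_bl + init.ldw_fl + init.dw_rest, rel=1e-12
        )

    def test_overweight_leaf_rejected(self):
        p = make_params()
        with pytest.raises(ValueError):
            initial_state_from(
                p, tdw_ini=0.4, ldw_bl_ini=0.51, qs_bl_ini=7.0, qs_rest_ini=1.0
            )

    def test_parameter_validation_catches_bad_values(self):
        p = make_params()
        bad = dataclasses.replace(p, eps_pot=1.5)
        with pytest.raises(ValueError, match="eps_pot"):
            bad.validate()
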