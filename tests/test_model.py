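"""Unit and property tests for the ODE model core."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qnq.model import (COMPLEX, GROWTH, REGROWTH, SIMPLE, STARVATION,
                       ModelParams, Phase, PopulationState, growth_rhs,
                       integrate_phase, lag_schedule, regrowth_rhs,
                       starvation_rhs)

from conftest import rk4_integrate


class TestRhsLimits:
    def test_growth_at_zero_resource_is_pure_differentiation(self, params):
        state = PopulationState(q=0.0, nq=1e6, resource=0.0, recyclable=0.0)
        d = growth_rhs(state, params)
        assert d.nq == pytest.approx(-params.sigma_max * 1e6)
        assert d.q == pytest.approx(params.sigma_max * 1e6)
        assert d.resource == 0.0
        assert d.recyclable == 0.0

    def test_growth_saturates_far_from_depletion(self, params):
        r = 1e4 * max(params.k_m, params.k_diff)
        state = PopulationState(q=0.0, nq=1e6, resource=r, recyclable=0.0)
        d = growth_rhs(state, params)
        assert d.nq == pytest.approx(params.v_max * 1e6, rel=1e-3)
        assert abs(d.q) < 1e-3 * params.sigma_max * 1e6

    def test_negative_state_rejected(self, params):
        bad = PopulationState(q=-1.0, nq=0.0, resource=0.0, recyclable=0.0)
        with pytest.raises(ValueError, match="negative"):
            growth_rhs(bad, params)

    def test_starvation_with_all_rates_zero_is_frozen(self):
        p = ModelParams(d_q=0.0, d_nq=0.0, tau=0.0, v_max=0.0)
        state = PopulationState(1e6, 1e6, 0.0, 1e5)
        d = starvation_rhs(state, p, Phase(STARVATION, COMPLEX))
        assert d.as_array() == pytest.approx(np.zeros(4))

    def test_starvation_requires_starvation_phase(self, params):
        state = PopulationState(1e6, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="phase"):
            starvation_rhs(state, params, Phase(GROWTH))

    def test_recyclable_pool_inert_in_simple_environment(self, params):
        state = PopulationState(0.0, 1e6, 0.0, 1e7)
        d_simple = starvation_rhs(state, params, Phase(STARVATION, SIMPLE))
        assert d_simple.nq == pytest.approx(-params.d_nq * 1e6)
        assert d_simple.recyclable == 0.0
        d_complex = starvation_rhs(state, params, Phase(STARVATION, COMPLEX))
        assert d_complex.nq > d_simple.nq  # residual-nutrient division

    def test_regrowth_everyone_lagged_is_inert(self, params):
        state = PopulationState(1e6, 1e6, 3.2e7, 0.0)
        d = regrowth_rhs(state, params, t_elapsed=0.1, lags=(1.5, 2.2))
        assert d.as_array() == pytest.approx(np.zeros(4))

    def test_regrowth_without_resource_adds_no_biomass(self, params):
        state = PopulationState(0.0, 1e6, 0.0, 0.0)
        d = regrowth_rhs(state, params, t_elapsed=10.0, lags=(0.0, 0.0))
        assert d.q + d.nq == pytest.approx(0.0)

    def test_regrowth_negative_time_rejected(self, params):
        state = PopulationState(1e6, 0.0, 3.2e7, 0.0)
        with pytest.raises(ValueError, match="t_elapsed"):
            regrowth_rhs(state, params, t_elapsed=-1.0, lags=(1.0, 1.0))


class TestLagSchedule:
    def test_zero_slopes_give_baselines(self):
        p = ModelParams(lag_q_slope=0.0, lag_nq_slope=0.0)
        assert lag_schedule(p, 5.0) == (p.lag_q0, p.lag_nq0)

    def test_week6_lags_match_measured_monoculture_values(self, params):
        lag_q, lag_nq = lag_schedule(params, 6.0)
        assert lag_nq == pytest.approx(9.4)
        assert lag_q == pytest.approx(1.6)

    def test_lags_clamped_at_zero(self):
        p = ModelParams(lag_nq_slope=-1.0)
        assert lag_schedule(p, 10.0)[1] == 0.0

    def test_negative_weeks_rejected(self, params):
        with pytest.raises(ValueError):
            lag_schedule(params, -1.0)


class TestIntegratePhase:
    def test_zero_duration_returns_initial_state(self, params):
        s0 = PopulationState(1e6, 2e6, 3e6, 4e6)
        traj = integrate_phase(s0, params, Phase(GROWTH), duration=0.0)
        assert len(traj) == 1
        assert traj.final_state == s0

    def test_pure_q_starvation_matches_exponential_closed_form(self):
        p = ModelParams(tau=0.0, epsilon=0.0)
        q0 = 1e6
        traj = integrate_phase(PopulationState(q0, 0.0, 0.0, 0.0), p,
                               Phase(STARVATION, SIMPLE), duration=672.0,
                               output_step=24.0)
        expected = q0 * np.exp(-p.d_q * traj.times)
        np.testing.assert_allclose(traj.q, expected, rtol=1e-6)

    def test_growth_phase_conserves_cell_equivalents(self, params):
        # integrate to resource exhaustion: total new cells == yield * R0
        nq0, r0 = 1e5, 3.2e7
        traj = integrate_phase(PopulationState(0.0, nq0, r0, 0.0), params,
                               Phase(GROWTH), duration=48.0, output_step=1.0)
        final = traj.final_state
        assert final.resource < 1e-3 * r0
        assert final.q + final.nq == pytest.approx(
            nq0 + params.yield_coeff * r0, rel=1e-6)

    def test_output_resolution_does_not_affect_dynamics(self, params):
        s0 = PopulationState(1e6, 1e6, 3.2e7, 0.0)
        phase = Phase(REGROWTH, lags=(1.5, 2.2))
        coarse = integrate_phase(s0, params, phase, 24.0, output_step=1.0)
        fine = integrate_phase(s0, params, phase, 24.0, output_step=0.5)
        np.testing.assert_allclose(fine.y[::2], coarse.y, rtol=1e-6, atol=1e-3)

    def test_tightening_tolerance_changes_final_biomass_below_0p1pct(self, params):
        s0 = PopulationState(1e6, 1e6, 3.2e7, 0.0)
        phase = Phase(REGROWTH, lags=(1.5, 2.2))
        base = integrate_phase(s0, params, phase, 24.0, rtol=1e-8)
        tight = integrate_phase(s0, params, phase, 24.0, rtol=1e-9)
        rel = abs(base.biomass[-1] - tight.biomass[-1]) / tight.biomass[-1]
        assert rel < 1e-3

    def test_negative_duration_rejected(self, params):
        with pytest.raises(ValueError):
            integrate_phase(PopulationState(1e6, 0, 0, 0), params,
                            Phase(GROWTH), duration=-1.0)


class TestConservationProperties:
    def test_full_recycling_conserves_total_during_starvation(self):
        p = ModelParams(epsilon=1.0, yield_coeff=1.0)
        s0 = PopulationState(1e6, 5e5, 0.0, 2e5)
        traj = integrate_phase(s0, p, Phase(STARVATION, COMPLEX),
                               duration=500.0, output_step=50.0)
        totals = traj.y.sum(axis=1)
        np.testing.assert_allclose(totals, s0.total_cell_equivalents, rtol=1e-6)

    def test_monotone_biomass_loss_without_recycling(self, params):
        s0 = PopulationState(1e6, 5e5, 0.0, 0.0)
        traj = integrate_phase(s0, params, Phase(STARVATION, SIMPLE),
                               duration=1008.0, output_step=24.0)
        biomass = traj.biomass
        assert np.all(np.diff(biomass) <= 1e-9 * biomass[0])

    def test_complex_starvation_keeps_more_nq_than_simple(self, params):
        """Fine-grid Euler oracle: NQ under recycling dominates pointwise."""
        y0 = np.array([0.0, 2e6, 0.0, 1e6])
        from qnq.model import _starvation_rhs_arr
        dt, horizon = 0.02, 300.0
        y_s, y_c = y0.copy(), y0.copy()
        nq_simple, nq_complex = [], []
        for _ in range(int(horizon / dt)):
            y_s = y_s + dt * _starvation_rhs_arr(y_s, params, 0.0, False)
            y_c = y_c + dt * _starvation_rhs_arr(y_c, params, params.epsilon, True)
            nq_simple.append(y_s[1])
            nq_complex.append(y_c[1])
        assert np.all(np.array(nq_complex) >= np.array(nq_simple))
        # and the production solver agrees with the Euler endpoint
        traj = integrate_phase(PopulationState.from_array(y0), params,
                               Phase(STARVATION, COMPLEX), horizon,
                               output_step=horizon)
        assert traj.final_state.nq == pytest.approx(y_c[1], rel=5e-3)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    q0=st.floats(0.0, 1e7),
    nq0=st.floats(0.0, 1e7),
    u0=st.floats(0.0, 1e7),
    epsilon=st.floats(0.0, 1.0),
    env=st.sampled_from([SIMPLE, COMPLEX]),
)
def test_states_stay_nonnegative_during_starvation(q0, nq0, u0, epsilon, env):
    p = ModelParams(epsilon=epsilon)
    traj = integrate_phase(PopulationState(q0, nq0, 0.0, u0), p,
                           Phase(STARVATION, env), duration=200.0,
                           output_step=20.0)
    assert np.all(traj.y >= 0.0)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(lag_q=st.floats(0.0, 6.0), lag_nq=st.floats(0.0, 6.0))
def test_states_stay_nonnegative_during_regrowth(lag_q, lag_nq):
    p = ModelParams()
    traj = integrate_phase(PopulationState(1e6, 1e6, 3.2e7, 0.0), p,
                           Phase(REGROWTH, lags=(lag_q, lag_nq)),
                           duration=24.0, output_step=0.5)
    assert np.all(traj.y >= 0.0)


class TestRK4OracleAgreement:
    """The adaptive production solver must track a fixed-step RK4 oracle."""

    def test_growth_phase(self, params):
        from qnq.model import _growth_rhs_arr
        y0 = np.array([0.0, 1e5, 3.2e7, 0.0])
        oracle = rk4_integrate(lambda t, y: _growth_rhs_arr(y, params),
                               y0, 48.0, 1e-3)
        traj = integrate_phase(PopulationState.from_array(y0), params,
                               Phase(GROWTH), 48.0, output_step=48.0)
        np.testing.assert_allclose(traj.y[-1], oracle, rtol=1e-4, atol=1.0)
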