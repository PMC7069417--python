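"""Fixed points, steady states and discretization behaviour of the kinetic models."""

import numpy as np
import pytest

from vo2pipe.kinetics import (Model1Params, Model2Params, Model2State,
                              model1_step, model2_forcings, model2_step,
                              simulate, simulate_model1_many,
                              simulate_model2_many)

M1 = Model1Params(gain_g=10.0, tau=45.0)
M2 = Model2Params(v_delta=397.0, p_c=359.0, delta=79.0, s_gain=8.67,
                  tau_fast=43.0, tau_slow=199.0, t_fast=10.0, t_slow=113.0)
VO2R, VO2MAX = 300.0, 4400.0


class TestModel1Step:
    def test_fixed_point_is_preserved_bit_exactly(self):
        p = 200.0
        ss = VO2R + M1.gain_g * p
        assert model1_step(ss, p, 1.7, M1, VO2R) == ss

    def test_single_step_from_rest(self):
        # one Euler step: vo2r + (200*10)/45
        out = model1_step(VO2R, 200.0, 1.0, M1, VO2R)
        assert out == pytest.approx(VO2R + 2000.0 / 45.0)

    def test_steady_state_reached_after_five_tau(self):
        t = np.arange(0.0, 5 * M1.tau + 60.0, 1.0)
        p = np.full_like(t, 250.0)
        vo2 = simulate("m1", M1, p, t, vo2r=VO2R)
        assert vo2[-1] == pytest.approx(VO2R + M1.gain_g * 250.0, rel=0.01)

    def test_euler_matches_analytic_exponential_as_dt_shrinks(self):
        # step response has closed form vo2r + G*P*(1 - exp(-t/tau))
        errs = []
        for dt in (4.0, 1.0, 0.25):
            t = np.arange(0.0, 240.0 + dt / 2, dt)
            p = np.full_like(t, 150.0)
            vo2 = simulate("m1", M1, p, t, vo2r=VO2R)
            exact = VO2R + M1.gain_g * 150.0 * (1.0 - np.exp(-t / M1.tau))
            errs.append(np.max(np.abs(vo2 - exact)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 5.0  # mlO2/min at dt=0.25 s


class TestModel2Forcings:
    def test_slow_forcing_at_critical_power_is_v_delta(self):
        _, a_slow = model2_forcings(M2.p_c, M2, VO2MAX, VO2R)
        assert a_slow == pytest.approx(M2.v_delta)

    def test_fast_forcing_clamped_at_aerobic_reserve(self):
        a_fast, _ = model2_forcings(1000.0, M2, VO2MAX, VO2R)
        assert a_fast == VO2MAX - VO2R

    def test_supra_critical_forcings_sum_to_reserve(self):
        for p in (M2.p_c + 1, M2.p_c + 100, 2000.0):
            a_fast, a_slow = model2_forcings(p, M2, VO2MAX, VO2R)
            assert a_fast + a_slow == pytest.approx(VO2MAX - VO2R)


class TestModel2Step:
    def test_components_inactive_before_fast_delay(self):
        state = Model2State(t=0.0)
        new, vo2 = model2_step(state, 300.0, 2.0, M2, VO2MAX, VO2R)
        assert vo2 == VO2R
        assert new.comp_fast == 0.0 and new.comp_slow == 0.0

    def test_sub_critical_steady_state(self):
        p = 250.0
        t = np.arange(0.0, 10 * M2.tau_slow, 2.0)
        vo2 = simulate("m2", M2, np.full_like(t, p), t, vo2r=VO2R, vo2max=VO2MAX)
        expected = (VO2R + min(M2.s_gain * p, VO2MAX - VO2R)
                    + M2.v_delta * np.exp(-(M2.p_c - p) / M2.delta))
        assert vo2[-1] == pytest.approx(expected, rel=0.01)

    def test_supra_critical_steady_state_is_vo2max(self):
        t = np.arange(0.0, 10 * M2.tau_slow, 2.0)
        vo2 = simulate("m2", M2, np.full_like(t, M2.p_c + 60.0), t,
                       vo2r=VO2R, vo2max=VO2MAX)
        assert vo2[-1] == pytest.approx(VO2MAX, rel=0.01)

    def test_fixed_point_preserved_bit_exactly(self):
        p = 200.0
        a_fast, a_slow = model2_forcings(p, M2, VO2MAX, VO2R)
        state = Model2State(comp_fast=a_fast, comp_slow=a_slow, t=500.0)
        new, vo2 = model2_step(state, p, 1.3, M2, VO2MAX, VO2R)
        assert new.comp_fast == a_fast and new.comp_slow == a_slow
        assert vo2 == VO2R + a_fast + a_slow


class TestSimulate:
    def test_zero_length_power_gives_empty_prediction(self):
        out = simulate("m1", M1, np.empty(0), np.empty(0), vo2r=VO2R)
        assert out.size == 0

    def test_slow_component_never_activates_in_short_all_out_burst(self):
        # a 30-s sprint is shorter than the slow activation delay
        t = np.arange(0.0, 30.0, 1.0)
        p = np.full_like(t, 800.0)
        vo2 = simulate("m2", M2, p, t, vo2r=VO2R, vo2max=VO2MAX)
        # slow component zero throughout => vo2 stays below rest + fast clamp
        t2 = np.concatenate([t, [31.0]])
        p2 = np.concatenate([p, [800.0]])
        no_slow = Model2Params(v_delta=1e-6, p_c=M2.p_c, delta=M2.delta,
                               s_gain=M2.s_gain, tau_fast=M2.tau_fast,
                               tau_slow=M2.tau_slow, t_fast=M2.t_fast,
                               t_slow=M2.t_slow)
        ref = simulate("m2", no_slow, p2, t2, vo2r=VO2R, vo2max=VO2MAX)
        assert np.allclose(vo2, ref[:-1])

    def test_output_bounded_for_bounded_power(self, rng):
        t = np.cumsum(rng.uniform(1.0, 4.0, 400))
        p = rng.uniform(0.0, 900.0, 400)
        vo2 = simulate("m2", M2, p, t, vo2r=VO2R, vo2max=VO2MAX)
        assert np.all(vo2 >= VO2R - 1e-9)
        assert np.all(vo2 <= VO2MAX + M2.v_delta + 1e-9)

    def test_euler_stability_guard_raises_on_huge_step(self):
        t = np.array([0.0, 100.0, 200.0])
        p = np.array([100.0, 100.0, 100.0])
        with pytest.raises(ValueError, match="stability"):
            simulate("m1", Model1Params(10.0, 20.0), p, t, vo2r=VO2R)

    def test_onset_delays_slow_clock(self):
        # 60 s of rest before power: delay clock starts at exercise onset
        t = np.arange(0.0, 400.0, 2.0)
        p = np.where(t >= 60.0, 300.0, 0.0)
        vo2 = simulate("m2", M2, p, t, vo2r=VO2R, vo2max=VO2MAX)
        # during rest plus the fast activation delay nothing moves
        quiet = t <= 60.0 + M2.t_fast
        assert np.allclose(vo2[quiet], VO2R)


class TestBatchedSimulators:
    """The swarm-evaluation fast paths must agree with the reference stepper."""

    def test_model1_batch_matches_scalar(self, rng):
        t = np.cumsum(rng.uniform(1.0, 4.0, 300))
        p = rng.uniform(0.0, 400.0, 300)
        gains = np.array([6.0, 10.0, 14.0])
        taus = np.array([20.0, 45.0, 110.0])
        batch = simulate_model1_many(gains, taus, p, t, VO2R)
        for i in range(3):
            ref = simulate("m1", Model1Params(gains[i], taus[i]), p, t, vo2r=VO2R)
            np.testing.assert_allclose(batch[i], ref, rtol=1e-12)

    def test_model2_batch_matches_scalar(self, rng):
        t = np.cumsum(rng.uniform(1.0, 4.0, 300))
        p = rng.uniform(0.0, 500.0, 300)
        rows = np.array([
            [397.0, 359.0, 79.0, 8.67, 43.0, 199.0, 10.0, 113.0],
            [800.0, 280.0, 40.0, 11.0, 30.0, 250.0, 5.0, 60.0],
        ])
        batch = simulate_model2_many(rows, p, t, VO2R, VO2MAX)
        for i, row in enumerate(rows):
            params = Model2Params(*row)
            ref = simulate("m2", params, p, t, vo2r=VO2R, vo2max=VO2MAX)
            np.testing.assert_allclose(batch[i], ref, rtol=1e-12)
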