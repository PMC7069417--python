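"""Protocol construction, trace sampling, breath simulation and cohort statistics."""

import numpy as np
import pytest

from vo2pipe.synthetic import (NoiseConfig, SESSION_KINDS, make_cohort,
                               make_protocol, sample_power_trace,
                               simulate_breaths)


class TestMakeProtocol:
    def test_gxt_first_two_stages(self, profile):
        proto = make_protocol("GXT", profile)
        s0, s1 = proto.segments[0], proto.segments[1]
        assert (s0.shape, s0.duration, s0.power_start) == ("constant", 240.0, 100.0)
        assert (s1.shape, s1.duration, s1.power_start) == ("constant", 240.0, 140.0)

    def test_gxt_increment_is_40w_per_stage(self, profile):
        proto = make_protocol("GXT", profile)
        powers = [s.power_start for s in proto.segments]
        assert np.allclose(np.diff(powers)[:len(powers) - 2], 40.0)

    def test_test1_total_duration_includes_lead_in_rest(self, profile):
        # 240 s rest + 240 s at 100 W + 3 repetitions of 3 x 240 s bouts
        proto = make_protocol("TEST1", profile)
        assert proto.total_duration == pytest.approx(2640.0)
        assert proto.segments[0].power_start == 0.0

    def test_test1_bout_sequence(self, profile):
        proto = make_protocol("TEST1", profile, rest_s=0.0)
        powers = [s.power_start for s in proto.segments]
        expected = [100.0] + [profile.p2, profile.p3, profile.p1] * 3
        assert powers == pytest.approx(expected)

    def test_test2_endpoints_consistent_with_intensity_ordering(self, profile):
        proto = make_protocol("TEST2", profile, rest_s=0.0)
        for seg in proto.segments:
            assert profile.p1 <= seg.power_start <= profile.p3 + 1e-9
            assert profile.p1 <= seg.power_end <= profile.p3 + 1e-9
        assert proto.segments[0].power_start == pytest.approx(profile.p1)
        assert proto.segments[0].power_end == pytest.approx(profile.p3)

    def test_wingate_sprint_decays_thirty_percent(self, profile):
        proto = make_protocol("WINGATE", profile)
        sprint = proto.segments[1]
        assert sprint.duration == 30.0
        assert sprint.power_start == pytest.approx(profile.p_max_wingate)
        assert sprint.power_end == pytest.approx(0.7 * profile.p_max_wingate)

    def test_unknown_kind_raises(self, profile):
        with pytest.raises(ValueError, match="unknown session kind"):
            make_protocol("SWIM", profile)


class TestSamplePowerTrace:
    def test_zero_noise_reproduces_exact_protocol(self, profile):
        proto = make_protocol("TEST2", profile, rest_s=0.0)
        trace = sample_power_trace(proto, dt=1.0, noise_sd=0.0)
        # ramp start, constant bout values appear exactly
        assert trace.power[0] == pytest.approx(profile.p1)
        assert trace.t[1] - trace.t[0] == 1.0
        mid_p3 = (trace.t > 245) & (trace.t < 295)
        assert np.allclose(trace.power[mid_p3], profile.p3)

    def test_same_seed_bit_identical(self, profile):
        proto = make_protocol("TEST1", profile)
        a = sample_power_trace(proto, dt=1.0, noise_sd=3.0, seed=5)
        b = sample_power_trace(proto, dt=1.0, noise_sd=3.0, seed=5)
        np.testing.assert_array_equal(a.power, b.power)
        np.testing.assert_array_equal(a.cadence, b.cadence)

    def test_noisy_mean_over_constant_segment_near_prescription(self, profile):
        proto = make_protocol("TEST1", profile, rest_s=0.0)
        noise_sd = 5.0
        trace = sample_power_trace(proto, dt=1.0, noise_sd=noise_sd, seed=9)
        seg = (trace.t >= 0) & (trace.t < 240.0)  # first bout, 100 W
        m = seg.sum()
        assert abs(trace.power[seg].mean() - 100.0) < 3 * noise_sd / np.sqrt(m)

    def test_cadence_zero_during_rest(self, profile):
        proto = make_protocol("WINGATE", profile)
        trace = sample_power_trace(proto, dt=1.0, noise_sd=2.0, seed=1)
        assert np.all(trace.cadence[trace.t < 119] == 0.0)


class TestSimulateBreaths:
    def test_resting_vo2_approaches_vo2r_without_noise(self, profile, quiet_noise):
        proto = make_protocol("TEST1", profile, rest_s=0.0)
        # zero-power trace: reuse the Wingate rest by building a flat protocol
        from vo2pipe.synthetic import PowerTrace
        tau_fast = profile.true_m2.tau_fast
        t = np.arange(0.0, 12 * tau_fast + 60.0, 1.0)
        trace = PowerTrace(t=t, power=np.zeros_like(t), cadence=np.zeros_like(t))
        series = simulate_breaths(trace, profile, quiet_noise, seed=0)
        late = series.t > 10 * tau_fast
        assert np.all(np.abs(series.vo2[late] - profile.vo2r)
                      <= 0.02 * profile.vo2r)

    def test_breath_times_strictly_increasing_with_rf_bound(self, test2_session):
        _, series = test2_session
        dts = np.diff(series.t)
        assert np.all(dts > 0)

    def test_min_interval_bounded_by_max_rf(self, profile, quiet_noise):
        proto = make_protocol("TEST2", profile, rest_s=0.0)
        trace = sample_power_trace(proto, dt=1.0, noise_sd=0.0)
        series = simulate_breaths(trace, profile, quiet_noise, seed=2)
        assert np.min(np.diff(series.t)) >= 60.0 / profile.rf_max - 1e-9

    def test_rf_hr_inside_anchors_without_noise(self, profile, quiet_noise):
        proto = make_protocol("TEST1", profile)
        trace = sample_power_trace(proto, dt=1.0, noise_sd=0.0)
        series = simulate_breaths(trace, profile, quiet_noise, seed=4)
        assert np.all(series.rf >= profile.rf_rest - 1e-9)
        assert np.all(series.rf <= profile.rf_max + 1e-9)
        assert np.all(series.hr >= profile.hr_rest - 1e-9)
        assert np.all(series.hr <= profile.hr_max + 1e-9)

    def test_invalid_rate_produces_expected_corruption_count(self, profile):
        proto = make_protocol("TEST1", profile)
        trace = sample_power_trace(proto, dt=1.0, noise_sd=0.0)
        cfg = NoiseConfig(invalid_rate=0.05)
        series = simulate_breaths(trace, profile, cfg, seed=7)
        from vo2pipe.preprocess import filter_invalid_breaths
        n = len(series)
        _, n_removed = filter_invalid_breaths(series)
        # binomial: mean n*0.05, generous +-4 sigma window
        mean, sd = 0.05 * n, np.sqrt(n * 0.05 * 0.95)
        assert mean - 4 * sd <= n_removed <= mean + 4 * sd

    def test_same_seed_bit_identical(self, profile):
        proto = make_protocol("WINGATE", profile)
        trace = sample_power_trace(proto, dt=1.0, noise_sd=2.0, seed=3)
        a = simulate_breaths(trace, profile, NoiseConfig(), seed=8)
        b = simulate_breaths(trace, profile, NoiseConfig(), seed=8)
        np.testing.assert_array_equal(a.vo2, b.vo2)
        np.testing.assert_array_equal(a.t, b.t)


class TestMakeCohort:
    def test_cohort_ppo_mean_matches_population(self):
        profiles = make_cohort(1000, seed=42)
        ppos = np.array([p.ppo for p in profiles])
        assert abs(ppos.mean() - 335.0) < 3 * 44.0 / np.sqrt(1000)

    def test_every_profile_satisfies_orderings(self):
        for p in make_cohort(50, seed=7):
            assert 0 < p.p_vt1 < p.p_vt2 < p.ppo
            assert p.p1 < p.p2 < p.p3
            assert 0 < p.vo2r < p.vo2max
            assert p.rf_rest < p.rf_max and p.hr_rest < p.hr_max

    def test_threshold_powers_back_solved_from_intensity_formulas(self):
        # p1 = vt1/2 and p2 = midpoint(vt1, vt2) must invert exactly
        for p in make_cohort(20, seed=3):
            assert p.p_vt1 == pytest.approx(2 * p.p1)
            assert p.p_vt2 == pytest.approx(2 * p.p2 - p.p_vt1)
            assert p.p3 == pytest.approx(0.5 * (p.ppo - p.p_vt2) + p.p_vt2)

    def test_cohort_stable_under_extension(self):
        small = make_cohort(3, seed=5)
        large = make_cohort(6, seed=5)
        for a, b in zip(small, large):
            assert a.ppo == b.ppo and a.vo2max == b.vo2max

    def test_same_seed_identical_cohort(self):
        a = make_cohort(4, seed=9)
        b = make_cohort(4, seed=9)
        assert all(x == y for x, y in zip(a, b))
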