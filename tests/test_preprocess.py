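"""Validity filtering, breath alignment, normalization and windowing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vo2pipe.preprocess import (TRIAL_SPLITS, WindowedDataset,
                                align_to_breaths, assemble_trial,
                                build_windows, denormalize_channel,
                                filter_invalid_breaths, normalize_channel)
from vo2pipe.synthetic import BreathSeries, PowerTrace


def _series(n=100, seed=0):
    rng = np.random.default_rng(seed)
    t = np.cumsum(rng.uniform(1.5, 4.0, n))
    return BreathSeries(t=t, vo2=rng.uniform(300, 4000, n),
                        hr=rng.uniform(60, 190, n),
                        rf=rng.uniform(10, 60, n),
                        ve=rng.uniform(10, 150, n),
                        feo2=rng.uniform(14, 18, n),
                        feco2=rng.uniform(3, 6, n))


class TestFilterInvalidBreaths:
    def test_low_rf_breath_removed(self):
        s = _series(10)
        s.rf[3] = 1.0
        cleaned, n = filter_invalid_breaths(s)
        assert n == 1 and len(cleaned) == 9
        assert s.t[3] not in cleaned.t

    def test_all_in_range_unchanged(self):
        s = _series(50)
        cleaned, n = filter_invalid_breaths(s)
        assert n == 0
        np.testing.assert_array_equal(cleaned.t, s.t)

    def test_planted_violations_are_counted(self):
        s = _series(100, seed=3)
        s.rf[2] = 95.0
        s.rf[11] = 1.5
        s.ve[20] = 0.05
        s.feo2[33] = 21.0
        s.feo2[41] = 4.0
        s.feco2[55] = 0.5
        s.feco2[77] = 10.5
        cleaned, n = filter_invalid_breaths(s)
        assert n == 7
        assert len(cleaned) == 93

    def test_all_removed_raises(self):
        s = _series(5)
        s.rf[:] = 1.0
        with pytest.raises(ValueError, match="all breaths"):
            filter_invalid_breaths(s)


class TestAlignToBreaths:
    def test_constant_trace(self):
        t = np.arange(0.0, 100.0, 1.0)
        trace = PowerTrace(t=t, power=np.full_like(t, 200.0),
                           cadence=np.full_like(t, 90.0))
        bt = np.array([5.0, 12.0, 30.0, 77.0])
        p, c = align_to_breaths(trace, bt)
        assert np.allclose(p, 200.0) and np.allclose(c, 90.0)

    def test_linear_ramp_gives_interval_midpoint(self):
        t = np.arange(0.0, 100.0, 0.01)
        trace = PowerTrace(t=t, power=10.0 + 2.0 * t, cadence=np.zeros_like(t))
        bt = np.array([10.0, 20.0, 50.0])
        p, _ = align_to_breaths(trace, bt)
        # mean of a + b*t over (10, 20] is the value at the midpoint 15
        assert p[1] == pytest.approx(10.0 + 2.0 * 15.0, rel=1e-3)
        assert p[2] == pytest.approx(10.0 + 2.0 * 35.0, rel=1e-3)

    def test_matches_brute_force_sample_means(self, rng):
        t = np.arange(0.0, 60.0, 0.5)
        power = rng.uniform(0, 400, t.size)
        trace = PowerTrace(t=t, power=power, cadence=power / 4)
        bt = np.sort(rng.uniform(1.0, 59.0, 20))
        p, c = align_to_breaths(trace, bt)
        for k in range(1, bt.size):
            sel = (t > bt[k - 1]) & (t <= bt[k])
            if sel.any():
                assert p[k] == pytest.approx(power[sel].mean())

    def test_breath_outside_span_raises(self):
        t = np.arange(0.0, 10.0, 1.0)
        trace = PowerTrace(t=t, power=t, cadence=t)
        with pytest.raises(ValueError, match="outside"):
            align_to_breaths(trace, np.array([5.0, 30.0]))


class TestNormalization:
    def test_anchor_endpoints(self):
        x = np.array([300.0, 4400.0])
        out = normalize_channel(x, (300.0, 4400.0))
        assert out[0] == 0.0 and out[1] == 1.0

    def test_half_ppo_is_half(self):
        assert normalize_channel(np.array([167.5]), (0.0, 335.0))[0] == 0.5

    @given(st.floats(-500, 5000), st.floats(0, 100), st.floats(101, 5000))
    @settings(deadline=None, max_examples=100)
    def test_round_trip_identity(self, x, lo, hi):
        anchors = (lo, hi)
        x_arr = np.array([x])
        back = denormalize_channel(normalize_channel(x_arr, anchors), anchors)
        assert back[0] == pytest.approx(x, abs=1e-9 * max(1, abs(x)))

    def test_degenerate_anchors_raise(self):
        with pytest.raises(ValueError):
            normalize_channel(np.array([1.0]), (5.0, 5.0))


class TestBuildWindows:
    def test_sample_count_is_n_minus_n_past(self):
        ch = np.zeros((100, 4))
        vo2 = np.arange(100.0)
        ds = build_windows(ch, vo2, n_past=70)
        assert len(ds) == 30

    def test_degenerate_zero_past_gives_one_step_pairs(self):
        ch = np.random.default_rng(0).normal(size=(50, 4))
        vo2 = np.arange(50.0)
        ds = build_windows(ch, vo2, n_past=0)
        assert len(ds) == 49

    def test_window_contents_match_index_oracle(self, rng):
        ch = rng.normal(size=(120, 4))
        vo2 = rng.normal(size=120)
        n_past = 30
        ds = build_windows(ch, vo2, n_past=n_past)
        for j in rng.integers(0, len(ds), 10):
            np.testing.assert_array_equal(ds.X[j], ch[j:j + n_past])
            assert ds.y[j] == vo2[j + n_past]
            np.testing.assert_array_equal(ds.X[j][-1], ch[j + n_past - 1])

    def test_too_short_session_raises(self):
        with pytest.raises(ValueError, match="n_past"):
            build_windows(np.zeros((50, 4)), np.zeros(50), n_past=70)

    def test_order_stability_under_shuffle_and_resort(self, rng):
        # shuffling breath rows then sorting by time reproduces the dataset
        n = 90
        t = np.cumsum(rng.uniform(1, 3, n))
        ch = rng.normal(size=(n, 4))
        vo2 = rng.normal(size=n)
        perm = rng.permutation(n)
        order = np.argsort(t[perm])
        ds_a = build_windows(ch, vo2, n_past=20)
        ds_b = build_windows(ch[perm][order], vo2[perm][order], n_past=20)
        np.testing.assert_array_equal(ds_a.X, ds_b.X)
        np.testing.assert_array_equal(ds_a.y, ds_b.y)


class TestAssembleTrial:
    @pytest.fixture
    def sessions(self, rng):
        out = {}
        for kind, n in (("GXT", 120), ("TEST1", 150), ("TEST2", 110),
                        ("WINGATE", 90)):
            out[kind] = (rng.normal(size=(n, 4)), rng.normal(size=n))
        return out

    def test_trial1_test_contains_only_test1_samples(self, sessions):
        _, test = assemble_trial(sessions, 1, n_past=70)
        assert set(test.session_id) == {"TEST1"}

    def test_train_test_sessions_disjoint_and_cover_all(self):
        for trial in (1, 2):
            split = TRIAL_SPLITS[trial]
            assert not set(split.train_sessions) & set(split.test_sessions)
            assert set(split.train_sessions) | set(split.test_sessions) \
                == {"GXT", "TEST1", "TEST2", "WINGATE"}

    def test_sample_counts_sum_over_sessions(self, sessions):
        train, test = assemble_trial(sessions, 2, n_past=70)
        expected_train = sum(sessions[k][1].size - 70
                             for k in TRIAL_SPLITS[2].train_sessions)
        assert len(train) == expected_train
        assert len(test) == sessions["WINGATE"][1].size - 70

    def test_missing_session_raises(self, sessions):
        del sessions["WINGATE"]
        with pytest.raises(ValueError, match="missing"):
            assemble_trial(sessions, 2, n_past=70)

    def test_no_nans_in_tensors(self, sessions):
        train, test = assemble_trial(sessions, 1, n_past=70)
        for ds in (train, test):
            assert np.isfinite(ds.X).all() and np.isfinite(ds.y).all()
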