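"""Closed-loop paradigm: detection, cycle extraction, the +/-10% rule,
and the infant-controlled trial state machine."""

import numpy as np
import pytest

from ibsense import paradigm, synth
from ibsense.exceptions import InsufficientDataError, SequencingError
from ibsense.paradigm import TaskConfig
from ibsense.synth import RespTrace


def _pulse_trace(onsets_ms, fs_hz=1000.0, total_ms=6000.0, height=1.0, pulse_ms=20):
    n = int(total_ms * fs_hz / 1000) + 1
    s = np.zeros(n)
    for onset in onsets_ms:
        i = int(onset * fs_hz / 1000)
        s[i : i + int(pulse_ms * fs_hz / 1000)] = height
    return RespTrace(samples=s, fs_hz=fs_hz)


class TestThresholdDetection:
    def test_square_pulses_detected_at_onsets(self):
        onsets = np.arange(500, 5500, 500)
        trace = _pulse_trace(onsets)
        train = paradigm.threshold_detect_rpeaks(trace, threshold=0.5)
        assert train.source == "detected"
        np.testing.assert_allclose(train.event_times, onsets, atol=1.0)
        np.testing.assert_allclose(np.diff(train.event_times), 500.0, atol=1.0)

    def test_threshold_above_trace_yields_empty_train(self):
        trace = _pulse_trace([1000, 2000], height=1.0)
        train = paradigm.threshold_detect_rpeaks(trace, threshold=2.0)
        assert train.event_times.size == 0

    def test_subthreshold_pulse_missed_exactly_once(self):
        onsets = np.arange(500, 5500, 500)
        trace = _pulse_trace(onsets, height=1.0)
        weak = int(onsets[4])  # one pulse stays below threshold
        s = trace.samples.copy()
        s[weak : weak + 20] = 0.3
        train = paradigm.threshold_detect_rpeaks(
            RespTrace(s, trace.fs_hz), threshold=0.5
        )
        assert train.event_times.size == onsets.size - 1
        missed = set(np.round(onsets)) - set(np.round(train.event_times))
        assert missed == {weak}

    def test_refractory_suppresses_double_counts(self):
        # pulse pairs 100 ms apart: second crossing falls inside refractory
        onsets = [1000, 1100, 2000, 2100]
        trace = _pulse_trace(onsets)
        train = paradigm.threshold_detect_rpeaks(trace, threshold=0.5, refractory_ms=200)
        assert train.event_times.size == 2


class TestMeanIbi:
    def test_even_spacing(self):
        train = synth.RPeakTrain(np.array([0.0, 500.0, 1000.0]), 500.0)
        assert paradigm.mean_ibi(train) == 500.0

    def test_uneven_spacing_averages(self):
        train = synth.RPeakTrain(np.array([0.0, 400.0, 1000.0]), 500.0)
        assert paradigm.mean_ibi(train) == pytest.approx(500.0)

    def test_matches_brute_force_on_random_train(self):
        train = synth.simulate_rpeak_train(430, 40, 60_000, seed=3)
        window = (5_000.0, 45_000.0)
        t = train.event_times
        inside = t[(t >= window[0]) & (t < window[1])]
        brute = np.diff(inside).mean()
        assert paradigm.mean_ibi(train, window) == pytest.approx(brute, rel=1e-12)

    def test_sparse_window_raises(self):
        train = synth.RPeakTrain(np.array([0.0, 500.0, 1000.0]), 500.0)
        with pytest.raises(InsufficientDataError):
            paradigm.mean_ibi(train, (600.0, 900.0))


class TestRespCycleExtraction:
    def test_pure_sinusoid_recovered_exactly(self):
        trace = synth.simulate_respiration(0.8, 1.5, 0, 20_000, 100, seed=1)
        freq, amp = paradigm.extract_resp_cycle(trace)
        assert freq == pytest.approx(0.8, abs=1e-6)
        assert amp == pytest.approx(1.5, abs=1e-6)

    def test_jittered_frequency_matches_cycle_counting_oracle(self):
        trace = synth.simulate_respiration(0.7, 1.0, 0.04, 60_000, 50, seed=6)
        freq, _ = paradigm.extract_resp_cycle(trace)
        # independent oracle: raw sample-level peak spacing, no refinement
        from scipy.signal import find_peaks

        s = trace.samples - trace.samples.mean()
        peaks, _ = find_peaks(s, height=0.0, distance=int(0.3 * 50))
        oracle = 1000.0 / np.mean(np.diff(trace.times_ms[peaks]))
        assert freq == pytest.approx(oracle, rel=5e-3)

    def test_constant_trace_raises(self):
        trace = RespTrace(np.zeros(500), fs_hz=50.0)
        with pytest.raises(InsufficientDataError):
            paradigm.extract_resp_cycle(trace)


class TestAsyncSchedules:
    @pytest.mark.parametrize(
        "ibi,direction,period",
        [(500.0, "slower", 550.0), (500.0, "faster", 450.0), (444.0, "faster", 399.6)],
    )
    def test_cardiac_period_is_exact_ten_percent(self, ibi, direction, period):
        sched = paradigm.make_async_schedule_cardiac(ibi, direction, 5000.0)
        got = sched.rate_source[1]
        assert abs(got - period) / period < 1e-9
        np.testing.assert_allclose(
            sched.event_times_ms, np.arange(sched.event_times_ms.size) * got
        )
        assert sched.direction == direction

    def test_cardiac_without_previous_sync_raises(self):
        with pytest.raises(SequencingError):
            paradigm.make_async_schedule_cardiac(None, "faster", 5000.0)

    @pytest.mark.parametrize(
        "freq,direction,expected",
        [(0.5, "faster", 0.55), (0.5, "slower", 0.45)],
    )
    def test_resp_frequency_is_exact_ten_percent(self, freq, direction, expected):
        sched = paradigm.make_async_schedule_resp(freq, 2.0, direction, 10_000.0)
        _, got_freq, got_amp = sched.rate_source
        assert got_freq == pytest.approx(expected, rel=1e-12)
        assert got_amp == 2.0

    def test_resp_schedule_renders_to_matching_zero_crossings(self):
        sched = paradigm.make_async_schedule_resp(0.5, 1.0, "faster", 21_000.0)
        _, freq, amp = sched.rate_source
        span_s = 21.0
        t = np.arange(0, span_s + 1e-9, 0.01)
        rendered = amp * np.sin(2 * np.pi * freq * t)
        # zeros at k/(2f); the t=0 zero starts a counted upward crossing
        expected = int(np.floor(2 * freq * span_s)) + 1
        assert synth.zero_crossings(rendered) == expected


class TestSessionStateMachine:
    def test_attentive_infant_sees_all_80_trials_at_max_duration(self, long_rpeak_train):
        cfg = TaskConfig.for_task("iBEATs")
        session = paradigm.run_session(
            long_rpeak_train, paradigm.AlwaysAttentive(), cfg, seed=1
        )
        assert len(session.trials) == 80
        assert all(t.duration_ms == 20_000.0 for t in session.trials)
        assert session.trials[0].condition == "sync"
        assert not session.aborted_by_lookaway

    def test_never_looking_infant_aborts_after_four_trials(self, long_rpeak_train):
        cfg = TaskConfig.for_task("iBEATs")
        session = paradigm.run_session(
            long_rpeak_train, paradigm.NeverLooks(), cfg, seed=1
        )
        assert len(session.trials) == 4
        assert session.aborted_by_lookaway
        assert all(t.lookaway_terminated for t in session.trials)
        assert all(t.duration_ms == 5000.0 for t in session.trials)

    def test_fussiness_signal_stops_session(self, long_rpeak_train):
        cfg = TaskConfig.for_task("iBEATs")
        session = paradigm.run_session(
            long_rpeak_train, paradigm.AlwaysAttentive(), cfg, seed=1, fussy_at_trial=10
        )
        assert len(session.trials) == 9
        assert session.aborted_by_fussiness

    @pytest.mark.parametrize("order_mode", ["fixed", "randomized"])
    def test_stochastic_sessions_respect_all_trial_invariants(
        self, long_rpeak_train, order_mode
    ):
        cfg = TaskConfig.for_task("iBEATs", order_mode=order_mode)
        policy = paradigm.StochasticGaze(mean_look_s=5.0, mean_away_s=1.6)
        for seed in range(25):
            session = paradigm.run_session(long_rpeak_train, policy, cfg, seed=seed)
            assert 1 <= len(session.trials) <= 80
            assert session.trials[0].condition == "sync"
            prev_ibi = None
            for tr in session.trials:
                assert 5000.0 <= tr.duration_ms <= 20_000.0
                assert 0.0 <= tr.looking_time_ms <= tr.duration_ms
                if tr.condition == "sync":
                    window = (tr.onset_ms, tr.onset_ms + tr.duration_ms)
                    ev = long_rpeak_train.event_times
                    expected = ev[(ev >= window[0]) & (ev < window[1])] - tr.onset_ms
                    np.testing.assert_array_equal(tr.schedule.event_times_ms, expected)
                    prev_ibi = paradigm.mean_ibi(long_rpeak_train, window)
                else:
                    period = tr.schedule.rate_source[1]
                    factor = period / prev_ibi
                    assert (
                        abs(factor - 0.9) < 1e-9 or abs(factor - 1.1) < 1e-9
                    ), f"async period off: {factor}"

    def test_respiratory_session_runs_and_obeys_bounds(self, long_resp_trace):
        cfg = TaskConfig.for_task("iBREATH")
        policy = paradigm.StochasticGaze()
        session = paradigm.run_session(long_resp_trace, policy, cfg, seed=5)
        assert session.trials[0].condition == "sync"
        prev_freq = None
        for tr in session.trials:
            assert 5000.0 <= tr.duration_ms <= 30_000.0
            if tr.condition == "sync":
                prev_freq, _ = paradigm.extract_resp_cycle(
                    long_resp_trace, (tr.onset_ms, tr.onset_ms + tr.duration_ms)
                )
            else:
                freq = tr.schedule.rate_source[1]
                ratio = freq / prev_freq
                assert abs(ratio - 1.1) < 1e-9 or abs(ratio - 0.9) < 1e-9

    def test_same_seed_reproduces_session(self, long_rpeak_train):
        cfg = TaskConfig.for_task("iBEATs", order_mode="randomized")
        policy = paradigm.StochasticGaze()
        a = paradigm.run_session(long_rpeak_train, policy, cfg, seed=4)
        b = paradigm.run_session(long_rpeak_train, policy, cfg, seed=4)
        assert a.to_trial_table().equals(b.to_trial_table())

    def test_short_recording_raises_clock_mismatch(self):
        short = synth.simulate_rpeak_train(450, 0, 10_000, seed=0)
        cfg = TaskConfig.for_task("iBEATs")
        with pytest.raises(Exception, match="cover the session clock"):
            paradigm.run_session(short, paradigm.AlwaysAttentive(), cfg, seed=0)


class TestOrderPlans:
    def test_fixed_order_starts_sync_with_occasional_repeats(self):
        order = paradigm.default_fixed_order(80)
        assert len(order) == 80
        assert order[0] == "sync"
        repeats = sum(a == b for a, b in zip(order, order[1:]))
        assert repeats > 0  # not strictly alternating
        assert {"sync", "async"} == set(order)

    def test_config_rejects_bad_bounds(self):
        with pytest.raises(Exception):
            TaskConfig(min_trial_s=20.0, max_trial_s=5.0)

    def test_wrong_physio_type_rejected(self, long_resp_trace):
        cfg = TaskConfig.for_task("iBEATs")
        with pytest.raises(Exception, match="R-peak"):
            paradigm.run_session(long_resp_trace, paradigm.AlwaysAttentive(), cfg, seed=0)
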