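"""Closed-loop iBEATs/iBREATH stimulus generation and trial control.

The cardiac task locks stimulus movement to the infant's R-peaks in
synchronous trials; asynchronous trials move at a constant period exactly 10%
faster or slower than the mean inter-beat interval of the preceding
synchronous trial.  The respiratory task couples stimulus size to the belt
signal in synchronous trials; asynchronous trials render a sinusoid at the
previous synchronous trial's mean amplitude and a frequency exactly 10%
faster or slower than its mean breathing frequency.

Trial control: the first trial is always synchronous; each trial lasts
between 5 s and the task maximum (20 s cardiac / 30 s respiratory); past the
minimum a trial terminates once the infant has looked away for 2 continuous
seconds; the session ends after 80 trials, after 4 consecutive
look-away-terminated trials, or on an external fussiness signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ibsense.exceptions import (
    ConfigurationError,
    InsufficientDataError,
    SequencingError,
)
from ibsense.synth import GazeStream, RespTrace, RPeakTrain, _rng, _seedseq

__all__ = [
    "StimulusSchedule",
    "TaskConfig",
    "Trial",
    "Session",
    "threshold_detect_rpeaks",
    "mean_ibi",
    "extract_resp_cycle",
    "make_async_schedule_cardiac",
    "make_async_schedule_resp",
    "run_session",
    "default_fixed_order",
    "AlwaysAttentive",
    "NeverLooks",
    "StochasticGaze",
]

DEFAULT_REFRACTORY_MS = 200.0  # infant heart rate stays below 300 bpm
ASYNC_FASTER_FACTOR = 0.9  # shorter period = faster
ASYNC_SLOWER_FACTOR = 1.1
ATTENTION_GETTER_S = 1.0


@dataclass(frozen=True)
class StimulusSchedule:
    """Timed movement onsets for one trial.

    ``rate_source`` records where the rhythm came from: ``"rpeak_locked"`` or
    ``"resp_locked"`` for synchronous trials, ``("fixed_period_ms", p)`` or
    ``("sinusoid", freq_hz, amp)`` for asynchronous ones.
    """

    event_times_ms: np.ndarray
    condition: str  # {"sync", "async"}
    rate_source: object
    direction: str = "n/a"  # {"faster", "slower", "n/a"}

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times_ms, dtype=float)
        object.__setattr__(self, "event_times_ms", times)
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("schedule event times must be strictly increasing")
        if self.condition == "sync" and self.direction != "n/a":
            raise ValueError("sync schedules carry direction 'n/a'")
        if self.condition == "async" and self.direction not in ("faster", "slower"):
            raise ValueError("async schedules need direction 'faster' or 'slower'")


@dataclass(frozen=True)
class TaskConfig:
    """Trial-control constants for one task."""

    task: str = "iBEATs"
    min_trial_s: float = 5.0
    max_trial_s: float = 20.0  # 30 for iBREATH
    lookaway_terminate_s: float = 2.0
    abort_after_consecutive_lookaway_trials: int = 4
    max_trials: int = 80
    min_trials_for_inclusion: int = 8  # 4 for iBREATH; 4 in longitudinal mode
    order_mode: str = "fixed"  # {"fixed", "randomized"}

    def __post_init__(self) -> None:
        if self.min_trial_s >= self.max_trial_s:
            raise ConfigurationError("min_trial_s must be below max_trial_s")
        counts = (
            self.abort_after_consecutive_lookaway_trials,
            self.max_trials,
            self.min_trials_for_inclusion,
        )
        if any(c <= 0 for c in counts):
            raise ConfigurationError("trial counts must be positive")
        if self.order_mode not in ("fixed", "randomized"):
            raise ConfigurationError("order_mode must be 'fixed' or 'randomized'")

    @classmethod
    def for_task(cls, task: str, order_mode: str = "fixed", longitudinal: bool = False) -> "TaskConfig":
        if task == "iBEATs":
            min_incl = 4 if longitudinal else 8
            return cls(task=task, max_trial_s=20.0, min_trials_for_inclusion=min_incl,
                       order_mode=order_mode)
        if task == "iBREATH":
            return cls(task=task, max_trial_s=30.0, min_trials_for_inclusion=4,
                       order_mode=order_mode)
        raise ConfigurationError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# Physiological feature extraction
# ---------------------------------------------------------------------------

def threshold_detect_rpeaks(
    trace: RespTrace,
    threshold: float,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> RPeakTrain:
    """Detect R-peaks as upward threshold crossings with a refractory period.

    Software emulation of a hardware fast-response output: an event fires at
    the first sample at or above ``threshold`` following a sample below it,
    and further events are suppressed for ``refractory_ms``.  A constant
    trace yields an empty train.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s = trace.samples
    times = trace.times_ms
    crossings = np.flatnonzero((s[:-1] < threshold) & (s[1:] >= threshold)) + 1
    events: list[float] = []
    last = -np.inf
    for i in crossings:
        t = times[i]
        if t - last >= refractory_ms:
            events.append(t)
            last = t
    events_arr = np.asarray(events)
    mean_ibi_ms = float(np.mean(np.diff(events_arr))) if events_arr.size >= 2 else float("nan")
    return RPeakTrain(event_times=events_arr, mean_ibi_ms=mean_ibi_ms, source="detected")


def mean_ibi(train: RPeakTrain, window: tuple[float, float] | None = None) -> float:
    """Arithmetic mean of successive inter-beat intervals inside ``window`` (ms)."""
    times = train.event_times
    if window is not None:
        t0, t1 = window
        times = times[(times >= t0) & (times < t1)]
    if times.size < 2:
        raise InsufficientDataError("mean IBI needs at least 2 events in the window")
    return float(np.mean(np.diff(times)))


def _parabolic_refine(s: np.ndarray, i: int) -> tuple[float, float]:
    """Refine an extremum at sample i by fitting a parabola through i-1, i, i+1.

    Returns (offset_in_samples, value).  Falls back to the raw sample at the
    array edges or when the parabola degenerates.
    """
    if i <= 0 or i >= s.size - 1:
        return 0.0, float(s[i])
    y0, y1, y2 = float(s[i - 1]), float(s[i]), float(s[i + 1])
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return 0.0, y1
    d = 0.5 * (y0 - y2) / denom
    val = y1 - 0.25 * (y0 - y2) * d
    return d, val


def extract_resp_cycle(
    trace: RespTrace, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Mean breathing frequency (Hz) and mean amplitude of a belt signal.

    The window is detrended by subtracting its mean; frequency comes from the
    mean peak-to-peak cycle length and amplitude from the mean half
    peak-to-trough excursion, both with parabolic sub-sample refinement.
    """
    s = trace.samples
    t = trace.times_ms
    if window is not None:
        t0, t1 = window
        m = (t >= t0) & (t < t1)
        s, t = s[m], t[m]
    if s.size < 3:
        raise InsufficientDataError("window too short for cycle extraction")
    s = s - np.mean(s)
    # breaths at <= 2 Hz: enforce at least 0.3 s between detected peaks
    distance = max(1, int(round(0.3 * trace.fs_hz)))
    peaks, _ = find_peaks(s, height=0.0, distance=distance)
    troughs, _ = find_peaks(-s, height=0.0, distance=distance)
    if peaks.size < 2 or troughs.size < 1:
        raise InsufficientDataError("no complete respiratory cycle in window")
    dt_ms = 1000.0 / trace.fs_hz
    peak_times = np.array([t[i] + _parabolic_refine(s, i)[0] * dt_ms for i in peaks])
    peak_vals = np.array([_parabolic_refine(s, i)[1] for i in peaks])
    trough_vals = np.array([-_parabolic_refine(-s, i)[1] for i in troughs])
    mean_cycle_ms = float(np.mean(np.diff(peak_times)))
    freq_hz = 1000.0 / mean_cycle_ms
    amp = float((np.mean(peak_vals) - np.mean(trough_vals)) / 2.0)
    return freq_hz, amp


# ---------------------------------------------------------------------------
# Asynchronous schedule construction (the +/-10% rule)
# ---------------------------------------------------------------------------

def _direction_factor(direction: str) -> float:
    if direction == "faster":
        return ASYNC_FASTER_FACTOR
    if direction == "slower":
        return ASYNC_SLOWER_FACTOR
    raise ValueError("direction must be 'faster' or 'slower'")


def make_async_schedule_cardiac(
    prev_sync_mean_ibi_ms: float | None,
    direction: str,
    trial_span_ms: float,
) -> StimulusSchedule:
    """Constant-period schedule at exactly 0.9x or 1.1x the previous sync IBI."""
    if prev_sync_mean_ibi_ms is None or not np.isfinite(prev_sync_mean_ibi_ms):
        raise SequencingError("asynchronous trial requires a preceding synchronous trial")
    period = prev_sync_mean_ibi_ms * _direction_factor(direction)
    n = int(np.floor(trial_span_ms / period)) + 1
    events = np.arange(n) * period
    return StimulusSchedule(
        event_times_ms=events,
        condition="async",
        rate_source=("fixed_period_ms", period),
        direction=direction,
    )


def make_async_schedule_resp(
    prev_freq_hz: float | None,
    prev_amp: float | None,
    direction: str,
    trial_span_ms: float,
) -> StimulusSchedule:
    """Sinusoidal schedule at exactly 1.1x or 0.9x the previous sync frequency.

    For the respiratory task "faster" means a higher frequency; the amplitude
    is carried over unchanged and the phase is 0 at trial onset.  Event times
    mark cycle onsets (phase-zero up-crossings).
    """
    if prev_freq_hz is None or not np.isfinite(prev_freq_hz) or prev_freq_hz <= 0:
        raise SequencingError("asynchronous trial requires a preceding synchronous trial")
    freq = prev_freq_hz * (1.1 if direction == "faster" else 0.9)
    if direction not in ("faster", "slower"):
        raise ValueError("direction must be 'faster' or 'slower'")
    period_ms = 1000.0 / freq
    n = int(np.floor(trial_span_ms / period_ms)) + 1
    events = np.arange(n) * period_ms
    return StimulusSchedule(
        event_times_ms=events,
        condition="async",
        rate_source=("sinusoid", freq, float(prev_amp)),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Gaze policies
# ---------------------------------------------------------------------------

class AlwaysAttentive:
    """Looks at the screen for the whole trial."""

    def trial_segments(self, rng: np.random.Generator, horizon_s: float):
        return [(horizon_s, True)]


class NeverLooks:
    """Never looks at the screen (forces the 4-trial abort rule)."""

    def trial_segments(self, rng: np.random.Generator, horizon_s: float):
        return [(horizon_s, False)]


@dataclass
class StochasticGaze:
    """Alternating look/look-away bouts with exponential durations.

    Starts each trial looking (the attention getter has just recaptured
    gaze); bout durations are exponential with the given means.
    """

    mean_look_s: float = 6.0
    mean_away_s: float = 1.5

    def trial_segments(self, rng: np.random.Generator, horizon_s: float):
        segments = []
        total = 0.0
        looking = True
        while total < horizon_s:
            mean = self.mean_look_s if looking else self.mean_away_s
            dur = float(rng.exponential(mean))
            segments.append((dur, looking))
            total += dur
            looking = not looking
        return segments


# ---------------------------------------------------------------------------
# Session state machine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    """One presented trial with its realized schedule and gaze outcome."""

    trial_index: int
    condition: str
    stimulus_id: str
    side: str
    onset_ms: float
    duration_ms: float
    looking_time_ms: float
    lookaway_terminated: bool
    schedule: StimulusSchedule


@dataclass
class Session:
    """An infant's ordered trial sequence for one task."""

    task: str
    config: TaskConfig
    trials: list[Trial] = field(default_factory=list)
    aborted_by_lookaway: bool = False
    aborted_by_fussiness: bool = False

    def to_trial_table(
        self, infant_id: str = "inf001", age_group: int = 9
    ) -> pd.DataFrame:
        from ibsense.synth import TRIAL_TABLE_COLUMNS

        rows = []
        for tr in self.trials:
            rows.append(
                {
                    "infant_id": infant_id,
                    "age_group": age_group,
                    "task": self.task,
                    "trial_index": tr.trial_index,
                    "condition": tr.condition,
                    "stimulus_id": tr.stimulus_id,
                    "side": tr.side,
                    "looking_time_ms": tr.looking_time_ms,
                    "trial_duration_ms": tr.duration_ms,
                    "artifact_flag": "none",
                    "technical_error": False,
                }
            )
        return pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)

    def schedules_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            src = tr.schedule.rate_source
            rows.append(
                {
                    "trial_index": tr.trial_index,
                    "condition": tr.condition,
                    "event_times": ";".join(f"{t:.3f}" for t in tr.schedule.event_times_ms),
                    "rate_source": src if isinstance(src, str) else ":".join(map(str, src)),
                    "direction": tr.schedule.direction,
                }
            )
        return pd.DataFrame(
            rows, columns=["trial_index", "condition", "event_times", "rate_source", "direction"]
        )


def default_fixed_order(n_trials: int = 80) -> tuple[str, ...]:
    """Documented default fixed condition order (replaceable constant).

    Alternating-leaning: strictly alternating except every 7th trial repeats
    the previous condition, so occasional sync-sync / async-async pairs occur.
    The first trial is always synchronous.
    """
    out: list[str] = []
    for i in range(n_trials):
        if i == 0:
            out.append("sync")
        elif i % 7 == 0:
            out.append(out[-1])
        else:
            out.append("async" if out[-1] == "sync" else "sync")
    return tuple(out)


def _fixed_plan(task: str, n_trials: int) -> list[dict]:
    """Fixed-order plan: conditions, fixed stimulus-condition mapping, sides
    balanced per condition, async directions alternating."""
    conditions = default_fixed_order(n_trials)
    stim = (
        {"sync": "star", "async": "cloud"}
        if task == "iBEATs"
        else {"sync": "apple", "async": "strawberry"}
    )
    plan = []
    side_count = {"sync": 0, "async": 0}
    async_count = 0
    for cond in conditions:
        side = "left" if side_count[cond] % 2 == 0 else "right"
        side_count[cond] += 1
        direction = "n/a"
        if cond == "async":
            direction = "faster" if async_count % 2 == 0 else "slower"
            async_count += 1
        plan.append({"condition": cond, "stimulus_id": stim[cond], "side": side,
                     "direction": direction})
    return plan


def _randomized_plan(task: str, n_trials: int, rng: np.random.Generator) -> list[dict]:
    """Randomized plan: first trial sync, then fair coin per trial; stimulus
    and side counterbalanced within condition; async direction uniform."""
    stimuli = ("star", "cloud") if task == "iBEATs" else ("apple", "strawberry")
    plan = []
    per_cond_count = {"sync": 0, "async": 0}
    for i in range(n_trials):
        cond = "sync" if i == 0 else ("sync" if rng.random() < 0.5 else "async")
        k = per_cond_count[cond]
        per_cond_count[cond] += 1
        stimulus = stimuli[int(rng.random() < 0.5)]
        side = ("left", "right")[k % 2]
        direction = "n/a"
        if cond == "async":
            direction = "faster" if rng.random() < 0.5 else "slower"
        plan.append({"condition": cond, "stimulus_id": stimulus, "side": side,
                     "direction": direction})
    return plan


def _trial_end_and_looking(
    segments: Sequence[tuple[float, float, bool]],
    min_s: float,
    max_s: float,
    terminate_s: float,
) -> tuple[float, float, bool]:
    """Resolve trial end time, looking time, and look-away termination.

    ``segments`` are (start_s, stop_s, looking) from trial onset.  The trial
    ends at the earliest ``max(away_start + terminate_s, min_s)`` covered by a
    continuous look-away, else at ``max_s``.
    """
    end = max_s
    lookaway_terminated = False
    for start, stop, looking in segments:
        if looking:
            continue
        candidate = max(start + terminate_s, min_s)
        if stop >= candidate and candidate <= max_s:
            end = candidate
            lookaway_terminated = True
            break
    looking_s = 0.0
    for start, stop, looking in segments:
        if looking:
            looking_s += max(0.0, min(stop, end) - min(start, end))
    return end, looking_s, lookaway_terminated


def _absolute_segments(raw: Iterable[tuple[float, bool]], horizon_s: float):
    """Convert (duration, looking) pairs to absolute (start, stop, looking)."""
    out = []
    t = 0.0
    for dur, looking in raw:
        if t >= horizon_s:
            break
        stop = min(t + dur, horizon_s)
        out.append((t, stop, looking))
        t += dur
    if not out or out[-1][1] < horizon_s:
        last_state = out[-1][2] if out else True
        out.append((out[-1][1] if out else 0.0, horizon_s, last_state))
    return out


def run_session(
    physio_source: RPeakTrain | RespTrace,
    gaze_policy,
    task_config: TaskConfig,
    seed,
    fussy_at_trial: int | None = None,
) -> Session:
    """Run the infant-controlled closed-loop session state machine.

    ``physio_source`` must cover the whole session on the session clock
    (milliseconds from session start); running past its end raises a
    configuration error.  ``gaze_policy`` provides per-trial look/look-away
    segments.  ``fussy_at_trial`` models the experimenter's judgment call: the
    session stops before that (1-based) trial number.
    """
    cfg = task_config
    if cfg.task == "iBEATs" and not isinstance(physio_source, RPeakTrain):
        raise ConfigurationError("iBEATs needs an R-peak train as physio source")
    if cfg.task == "iBREATH" and not isinstance(physio_source, RespTrace):
        raise ConfigurationError("iBREATH needs a respiration trace as physio source")
    rng = _rng(np.random.default_rng(_seedseq(seed)))
    if cfg.order_mode == "fixed":
        plan = _fixed_plan(cfg.task, cfg.max_trials)
    else:
        plan = _randomized_plan(cfg.task, cfg.max_trials, rng)

    if cfg.task == "iBEATs":
        physio_end_ms = float(physio_source.event_times[-1])
    else:
        physio_end_ms = float(physio_source.times_ms[-1])

    session = Session(task=cfg.task, config=cfg)
    t_ms = 0.0
    consecutive_lookaway = 0
    prev_sync_ibi: float | None = None
    prev_sync_resp: tuple[float, float] | None = None

    for idx, entry in enumerate(plan, start=1):
        if fussy_at_trial is not None and idx >= fussy_at_trial:
            session.aborted_by_fussiness = True
            break
        t_ms += ATTENTION_GETTER_S * 1000.0
        onset_ms = t_ms
        if onset_ms + cfg.max_trial_s * 1000.0 > physio_end_ms:
            raise ConfigurationError(
                "physiological recording does not cover the session clock"
            )
        raw = gaze_policy.trial_segments(rng, cfg.max_trial_s)
        segments = _absolute_segments(raw, cfg.max_trial_s)
        end_s, looking_s, lookaway_terminated = _trial_end_and_looking(
            segments, cfg.min_trial_s, cfg.max_trial_s, cfg.lookaway_terminate_s
        )
        duration_ms = end_s * 1000.0
        window = (onset_ms, onset_ms + duration_ms)

        if entry["condition"] == "sync":
            if cfg.task == "iBEATs":
                ev = physio_source.event_times
                ev = ev[(ev >= window[0]) & (ev < window[1])] - onset_ms
                schedule = StimulusSchedule(ev, "sync", "rpeak_locked")
                prev_sync_ibi = mean_ibi(physio_source, window)
            else:
                freq, amp = extract_resp_cycle(physio_source, window)
                prev_sync_resp = (freq, amp)
                # cycle landmarks: detrended zero-up-crossings inside the trial
                s = physio_source.samples
                tt = physio_source.times_ms
                m = (tt >= window[0]) & (tt < window[1])
                sw = s[m] - np.mean(s[m])
                ups = np.flatnonzero((sw[:-1] <= 0) & (sw[1:] > 0)) + 1
                ev = tt[m][ups] - onset_ms
                schedule = StimulusSchedule(ev, "sync", "resp_locked")
        else:
            direction = entry["direction"]
            if cfg.task == "iBEATs":
                schedule = make_async_schedule_cardiac(prev_sync_ibi, direction, duration_ms)
            else:
                if prev_sync_resp is None:
                    raise SequencingError(
                        "asynchronous trial requires a preceding synchronous trial"
                    )
                schedule = make_async_schedule_resp(
                    prev_sync_resp[0], prev_sync_resp[1], direction, duration_ms
                )

        session.trials.append(
            Trial(
                trial_index=idx,
                condition=entry["condition"],
                stimulus_id=entry["stimulus_id"],
                side=entry["side"],
                onset_ms=onset_ms,
                duration_ms=duration_ms,
                looking_time_ms=looking_s * 1000.0,
                lookaway_terminated=lookaway_terminated,
                schedule=schedule,
            )
        )
        t_ms = onset_ms + duration_ms

        consecutive_lookaway = consecutive_lookaway + 1 if lookaway_terminated else 0
        if consecutive_lookaway >= cfg.abort_after_consecutive_lookaway_trials:
            session.aborted_by_lookaway = True
            break
    return session
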