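"""Synthetic physiology, gaze, and looking-time data with known ground truth.

Everything downstream of the eye tracker and the physiological amplifiers is
testable against data generated here: R-peak event trains, respiratory belt
traces, 500 Hz gaze streams, and reduced-form trial tables whose
between-infant preference heterogeneity and within-infant trial noise are set
explicitly.  All generators are bit-reproducible given (parameters, seed); the
trial-table generator spawns one independent substream per infant so that
growing ``n_infants`` never reshuffles earlier infants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RPeakTrain",
    "RespTrace",
    "GazeStream",
    "InfantProfile",
    "TRIAL_TABLE_COLUMNS",
    "simulate_rpeak_train",
    "simulate_respiration",
    "simulate_gaze_stream",
    "inject_artifacts",
    "simulate_looking_time_table",
    "subject_mean_diffs",
    "power_curve",
    "zero_crossings",
]

# Physiologically plausible inter-beat-interval range for infants (ms).
IBI_MIN_MS = 200.0
IBI_MAX_MS = 1500.0

# Default base looking time: midpoint of the 9-mo cardiac condition means
# (7020.62 and 5496.70 ms), the sample the reduced-form generator emulates.
DEFAULT_BASE_LT_MS = 6258.66
DEFAULT_TRIAL_DURATION_MS = 20_000.0

TRIAL_TABLE_COLUMNS = [
    "infant_id",
    "age_group",
    "task",
    "trial_index",
    "condition",
    "stimulus_id",
    "side",
    "looking_time_ms",
    "trial_duration_ms",
    "artifact_flag",
    "technical_error",
]


@dataclass(frozen=True)
class RPeakTrain:
    """ECG R-peak event times in ms from session start."""

    event_times: np.ndarray
    mean_ibi_ms: float
    source: str = "simulated"  # {"simulated", "detected"}

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", times)
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("R-peak times must be strictly increasing")

    @property
    def ibis_ms(self) -> np.ndarray:
        return np.diff(self.event_times)


@dataclass(frozen=True)
class RespTrace:
    """Sampled respiration-belt signal in arbitrary units."""

    samples: np.ndarray
    fs_hz: float
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if samples.size < 2:
            raise ValueError("a respiration trace needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("respiration samples must be finite")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.samples.size) * (1000.0 / self.fs_hz)


@dataclass(frozen=True)
class GazeStream:
    """Eye-tracker samples (nominally 500 Hz): times, screen coordinates, validity."""

    times_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    fs_hz: float = 500.0

    def __post_init__(self) -> None:
        for name in ("times_ms", "x_px", "y_px"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))
        n = self.times_ms.size
        if not (self.x_px.size == self.y_px.size == self.valid.size == n):
            raise ValueError("gaze fields must have equal length")
        if n >= 2 and not np.all(np.diff(self.times_ms) > 0):
            raise ValueError("gaze times must be strictly increasing")


@dataclass(frozen=True)
class InfantProfile:
    """Generating parameters for one simulated infant."""

    infant_id: str
    age_group: int = 9  # months; one of {3, 9, 18}
    preference_delta_ms: float = 0.0  # true mean LT(sync) - LT(async)
    between_sd_ms: float = 0.0
    within_sd_ms: float = 0.0
    lookaway_hazard_per_s: float = 0.1
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.between_sd_ms < 0 or self.within_sd_ms < 0:
            raise ValueError("SDs must be >= 0")
        if self.lookaway_hazard_per_s < 0:
            raise ValueError("lookaway hazard must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def simulate_rpeak_train(
    mean_ibi_ms: float,
    ibi_sd_ms: float,
    duration_ms: float,
    seed,
) -> RPeakTrain:
    """Simulate an infant R-peak train with Gaussian IBI variability.

    Inter-beat intervals are drawn from a Normal(mean_ibi_ms, ibi_sd_ms)
    truncated to the physiologically plausible [200, 1500] ms band
    (truncation by the distribution, not by clipping, so no point mass at the
    bounds).  The first event is at t = 0 and events cover [0, duration_ms].
    """
    if not IBI_MIN_MS <= mean_ibi_ms <= IBI_MAX_MS:
        raise ValueError(f"mean_ibi_ms must lie in [{IBI_MIN_MS}, {IBI_MAX_MS}]")
    if ibi_sd_ms < 0:
        raise ValueError("ibi_sd_ms must be >= 0")
    if duration_ms <= mean_ibi_ms:
        raise ValueError("duration_ms must exceed mean_ibi_ms")
    rng = _rng(seed)
    n_expect = int(duration_ms / mean_ibi_ms) + 2
    times = [0.0]
    while times[-1] <= duration_ms:
        if ibi_sd_ms == 0:
            gaps = np.full(n_expect, mean_ibi_ms)
        else:
            a = (IBI_MIN_MS - mean_ibi_ms) / ibi_sd_ms
            b = (IBI_MAX_MS - mean_ibi_ms) / ibi_sd_ms
            gaps = stats.truncnorm.rvs(
                a, b, loc=mean_ibi_ms, scale=ibi_sd_ms, size=n_expect, random_state=rng
            )
        times = np.concatenate([np.asarray(times), times[-1] + np.cumsum(gaps)])
        times = list(times)
    times = np.asarray(times)
    times = times[times <= duration_ms]
    return RPeakTrain(event_times=times, mean_ibi_ms=mean_ibi_ms, source="simulated")


def simulate_respiration(
    freq_hz: float,
    amp: float,
    freq_jitter: float,
    duration_ms: float,
    fs_hz: float,
    seed,
) -> RespTrace:
    """Simulate a respiration-belt trace as a frequency-jittered sinusoid.

    The instantaneous frequency is redrawn once per cycle from
    Normal(freq_hz, freq_jitter) (floored at 0.05 Hz) and the phase is
    accumulated continuously, so zero jitter gives an exact sinusoid
    ``amp * sin(2*pi*freq_hz*t)``.  Samples cover [0, duration_ms] inclusive.
    """
    if not 0.1 <= freq_hz <= 2.0:
        raise ValueError("freq_hz must lie in [0.1, 2.0]")
    if fs_hz < 10 * freq_hz:
        raise ValueError("fs_hz must be at least 10x freq_hz")
    if freq_jitter < 0:
        raise ValueError("freq_jitter must be >= 0")
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    rng = _rng(seed)
    n = int(round(duration_ms * fs_hz / 1000.0)) + 1
    t = np.arange(n) / fs_hz
    if freq_jitter == 0:
        phase = 2 * np.pi * freq_hz * t
    else:
        # piecewise-constant frequency per cycle, continuous phase
        phase = np.empty(n)
        phi = 0.0
        i = 0
        while i < n:
            f = max(0.05, rng.normal(freq_hz, freq_jitter))
            # number of samples to finish this cycle at frequency f
            dphi = 2 * np.pi * f / fs_hz
            n_cycle = max(1, int(np.ceil((2 * np.pi) / dphi)))
            j = min(n, i + n_cycle)
            phase[i:j] = phi + dphi * np.arange(j - i)
            phi = phase[j - 1] + dphi if j > i else phi
            i = j
    return RespTrace(samples=amp * np.sin(phase), fs_hz=fs_hz, t0_ms=0.0)


def zero_crossings(samples: np.ndarray) -> int:
    """Count zero crossings with an upward-inclusive sign-change rule.

    A crossing is counted between samples i and i+1 when
    ``s[i] <= 0 < s[i+1]`` or ``s[i] >= 0 > s[i+1]``, so a sample landing
    exactly on zero starts (not doubles) a crossing.
    """
    s = np.asarray(samples, dtype=float)
    up = (s[:-1] <= 0) & (s[1:] > 0)
    down = (s[:-1] >= 0) & (s[1:] < 0)
    return int(np.count_nonzero(up | down))


def simulate_gaze_stream(
    look_segments: Sequence[tuple[float, float, bool]],
    aoi_center: tuple[float, float] = (480.0, 540.0),
    off_screen: tuple[float, float] = (-100.0, -100.0),
    scatter_px: float = 15.0,
    fs_hz: float = 500.0,
    seed=0,
) -> GazeStream:
    """Render a gaze stream from (start_ms, stop_ms, looking) segments.

    While looking, samples scatter around ``aoi_center`` with Gaussian noise;
    while away, samples sit off-screen and are flagged invalid.  Segment
    boundaries are treated half-open [start, stop).
    """
    if not look_segments:
        raise ValueError("need at least one segment")
    rng = _rng(seed)
    t0 = look_segments[0][0]
    t1 = look_segments[-1][1]
    period = 1000.0 / fs_hz
    times = np.arange(t0, t1, period)
    x = np.full(times.size, off_screen[0])
    y = np.full(times.size, off_screen[1])
    valid = np.zeros(times.size, dtype=bool)
    for start, stop, looking in look_segments:
        m = (times >= start) & (times < stop)
        if looking:
            k = int(np.count_nonzero(m))
            x[m] = aoi_center[0] + rng.normal(0, scatter_px, size=k)
            y[m] = aoi_center[1] + rng.normal(0, scatter_px, size=k)
            valid[m] = True
    return GazeStream(times_ms=times, x_px=x, y_px=y, valid=valid, fs_hz=fs_hz)


_ARTIFACT_TYPES = ("dropped_rpeak", "movement_transient")


def inject_artifacts(
    signals: Sequence[RPeakTrain | RespTrace],
    artifact_spec: dict,
    seed,
) -> tuple[list, np.ndarray]:
    """Corrupt a per-trial list of physiological signals, returning truth flags.

    ``artifact_spec`` has keys ``rate`` (per-trial corruption probability) and
    ``type`` ("dropped_rpeak" removes 1..3 interior R-peaks;
    "movement_transient" adds a large boxcar excursion to a respiration
    trace).  Uncorrupted trials are returned unchanged (the same object), and
    ``truth_flags[i]`` is True exactly for the corrupted trials.
    """
    rate = float(artifact_spec.get("rate", 0.0))
    kind = artifact_spec.get("type", "dropped_rpeak")
    if kind not in _ARTIFACT_TYPES:
        raise ValueError(f"unknown artifact type {kind!r}; expected one of {_ARTIFACT_TYPES}")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("artifact rate must lie in [0, 1]")
    rng = _rng(seed)
    out = []
    flags = np.zeros(len(signals), dtype=bool)
    for i, sig in enumerate(signals):
        hit = rng.random() < rate
        if not hit:
            out.append(sig)
            continue
        if kind == "dropped_rpeak":
            if not isinstance(sig, RPeakTrain):
                raise ValueError("dropped_rpeak artifacts apply to RPeakTrain signals")
            n = sig.event_times.size
            if n <= 2:
                out.append(sig)
                continue
            n_drop = int(rng.integers(1, min(3, n - 2) + 1))
            drop = rng.choice(np.arange(1, n - 1), size=n_drop, replace=False)
            keep = np.setdiff1d(np.arange(n), drop)
            out.append(
                RPeakTrain(sig.event_times[keep], sig.mean_ibi_ms, source=sig.source)
            )
        else:
            if not isinstance(sig, RespTrace):
                raise ValueError("movement_transient artifacts apply to RespTrace signals")
            s = sig.samples.copy()
            n = s.size
            width = max(2, n // 10)
            start = int(rng.integers(0, n - width))
            scale = 5.0 * max(1.0, float(np.std(s)))
            s[start : start + width] += scale
            out.append(RespTrace(s, sig.fs_hz, sig.t0_ms))
        flags[i] = True
    return out, flags


def _truncnorm_draw(
    rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Normal(mu, sd) truncated to [lo, hi] by the truncated distribution."""
    if sd == 0:
        return np.full(size, np.clip(mu, lo, hi))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _draw_infant_lts(
    rng: np.random.Generator,
    delta_ms: float,
    between_sd_ms: float,
    within_sd_ms: float,
    n_trials_per_cond: int,
    base_lt_ms: float,
    trial_duration_ms: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (sync, async) trial looking times for one infant.

    The infant's true preference delta_i ~ Normal(delta_ms, between_sd_ms) is
    split symmetrically around the base looking time; trial LTs are Normal
    around the condition mean with SD ``within_sd_ms``, truncated to
    [0, trial_duration_ms].
    """
    delta_i = rng.normal(delta_ms, between_sd_ms) if between_sd_ms > 0 else delta_ms
    mu_sync = base_lt_ms + delta_i / 2.0
    mu_async = base_lt_ms - delta_i / 2.0
    sync = _truncnorm_draw(rng, mu_sync, within_sd_ms, 0.0, trial_duration_ms, n_trials_per_cond)
    asyn = _truncnorm_draw(rng, mu_async, within_sd_ms, 0.0, trial_duration_ms, n_trials_per_cond)
    return sync, asyn


def simulate_looking_time_table(
    n_infants: int,
    delta_ms: float,
    between_sd_ms: float,
    within_sd_ms: float,
    n_trials_per_cond: int,
    seed,
    *,
    task: str = "iBEATs",
    age_group: int = 9,
    base_lt_ms: float = DEFAULT_BASE_LT_MS,
    trial_duration_ms: float = DEFAULT_TRIAL_DURATION_MS,
) -> pd.DataFrame:
    """Simulate a long-format trial table with hierarchical truncated-Normal LTs.

    Per infant i the true condition difference delta_i is drawn from
    Normal(delta_ms, between_sd_ms); trial looking times are drawn from a
    Normal(mu_cond_i, within_sd_ms) truncated (by resampling, not clipping)
    to [0, trial_duration_ms].  Conditions alternate starting with sync, as
    the paradigm engine would present them, and sides are counterbalanced.

    One global seed spawns an independent substream per infant, so increasing
    ``n_infants`` extends the table without reshuffling earlier infants.
    """
    if n_infants < 2:
        raise ValueError("n_infants must be >= 2")
    if between_sd_ms < 0 or within_sd_ms < 0:
        raise ValueError("SDs must be >= 0")
    if n_trials_per_cond < 1:
        raise ValueError("n_trials_per_cond must be >= 1")
    streams = _seedseq(seed).spawn(n_infants)
    records: dict[str, list] = {c: [] for c in TRIAL_TABLE_COLUMNS}
    stimuli = ("star", "cloud") if task == "iBEATs" else ("apple", "strawberry")
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sync, asyn = _draw_infant_lts(
            rng, delta_ms, between_sd_ms, within_sd_ms,
            n_trials_per_cond, base_lt_ms, trial_duration_ms,
        )
        infant = f"inf{i + 1:03d}"
        for j in range(n_trials_per_cond):
            for k, (cond, lt) in enumerate((("sync", sync[j]), ("async", asyn[j]))):
                idx = 2 * j + k + 1
                records["infant_id"].append(infant)
                records["age_group"].append(age_group)
                records["task"].append(task)
                records["trial_index"].append(idx)
                records["condition"].append(cond)
                records["stimulus_id"].append(stimuli[k])
                records["side"].append("left" if (idx + i) % 2 else "right")
                records["looking_time_ms"].append(float(lt))
                records["trial_duration_ms"].append(float(trial_duration_ms))
                records["artifact_flag"].append("none")
                records["technical_error"].append(False)
    return pd.DataFrame(records, columns=TRIAL_TABLE_COLUMNS)


def subject_mean_diffs(
    n_infants: int,
    delta_ms: float,
    between_sd_ms: float,
    within_sd_ms: float,
    n_trials_per_cond: int,
    seed,
    *,
    base_lt_ms: float = DEFAULT_BASE_LT_MS,
    trial_duration_ms: float = DEFAULT_TRIAL_DURATION_MS,
) -> np.ndarray:
    """Per-infant mean LT(sync) - mean LT(async) from the same generative model.

    Light-weight path used by the power simulator; draws from the identical
    hierarchy as :func:`simulate_looking_time_table` without building a table.
    """
    streams = _seedseq(seed).spawn(n_infants)
    diffs = np.empty(n_infants)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sync, asyn = _draw_infant_lts(
            rng, delta_ms, between_sd_ms, within_sd_ms,
            n_trials_per_cond, base_lt_ms, trial_duration_ms,
        )
        diffs[i] = sync.mean() - asyn.mean()
    return diffs


def power_curve(
    n_grid: Sequence[int],
    profile: dict,
    reps: int,
    alpha: float,
    seed,
) -> pd.DataFrame:
    """Monte-Carlo paired-t detection rate as a function of sample size.

    ``profile`` carries the generative parameters (``delta_ms``,
    ``between_sd_ms``, ``within_sd_ms``, ``n_trials_per_cond`` and optionally
    ``base_lt_ms``/``trial_duration_ms``).  For each n in ``n_grid``, ``reps``
    tables are simulated and the fraction of two-tailed paired-t rejections at
    ``alpha`` is recorded.
    """
    if len(n_grid) == 0:
        raise ValueError("n_grid must be non-empty")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    base = profile.get("base_lt_ms", DEFAULT_BASE_LT_MS)
    dur = profile.get("trial_duration_ms", DEFAULT_TRIAL_DURATION_MS)
    rows = []
    # Shared replicate streams across all n (common random numbers): the first
    # n infant substreams coincide for nested sample sizes, which sharpens the
    # monotonicity of the estimated power curve.
    rep_seeds = _seedseq(seed).spawn(reps)
    for n in n_grid:
        rejections = 0
        for r in range(reps):
            diffs = subject_mean_diffs(
                int(n),
                profile["delta_ms"],
                profile["between_sd_ms"],
                profile["within_sd_ms"],
                profile["n_trials_per_cond"],
                rep_seeds[r],
                base_lt_ms=base,
                trial_duration_ms=dur,
            )
            t, p = stats.ttest_1samp(diffs, 0.0)[:2]
            rejections += p < alpha
        rows.append({"n": int(n), "detection_rate": rejections / reps})
    return pd.DataFrame(rows)
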