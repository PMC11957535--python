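"""Exclusion, looking-time, outlier, and scoring rules.

Turns raw session output into analysis-ready per-infant summaries:

* looking time per trial = summed duration of valid gaze samples inside the
  stimulus AOI;
* trials flagged for technical problems or physiological artifacts (graded
  ``none``/``small``/``large`` so graded rejection rules can be expressed);
* a deterministic exclusion chain (technical -> artifact -> zero-LT ->
  SD outliers -> per-infant minimum trial count), each removal accounted for;
* the absolute proportional discrimination score
  ``|mean_sync - mean_async| / (mean_sync + mean_async)`` in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ibsense.exceptions import InsufficientDataError
from ibsense.synth import GazeStream

__all__ = [
    "AOI",
    "ExclusionPolicy",
    "ARTIFACT_KEEP_SETS",
    "compute_looking_time",
    "grade_cardiac_artifact",
    "grade_resp_artifact",
    "flag_physio_artifacts",
    "apply_exclusions",
    "reject_sd_outliers",
    "run_policy",
    "log_transform_lt",
    "subject_summaries",
]

ARTIFACT_FLAGS = ("none", "small", "large")

# Keep-sets per artifact rejection rule.  Flags grade severity: for the
# cardiac task ``small`` means >= 85% of R-peaks detected (but not all) and
# ``large`` means < 85%; for the respiratory task the grade follows the
# fraction of the trial overlapped by a movement transient.  Some rules from
# different source criteria coincide on this grading; they remain separate
# analysis paths in the multiverse because their defining criteria differ.
ARTIFACT_KEEP_SETS: dict[str, set[str]] = {
    "none": {"none", "small", "large"},
    "pct85": {"none", "small"},
    "small_included": {"none", "small"},
    "large_included": {"none", "small", "large"},
    "strict": {"none"},
    "amp_based": {"none", "small"},
    "freq_based": {"none"},
}

CARDIAC_PCT85 = 0.85
RESP_SMALL_OVERLAP = 0.2


@dataclass(frozen=True)
class AOI:
    """Screen-pixel rectangle derived from the stimulus' maximum excursion."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("AOI bounds must satisfy x_min < x_max and y_min < y_max")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)
        )


@dataclass(frozen=True)
class ExclusionPolicy:
    """One configuration of the preprocessing decision space.

    ``sd_k`` and ``min_trials`` accept ``None`` to switch the step off;
    ``artifact_scope`` controls whether artifact rejection touches only
    asynchronous trials or both conditions.
    """

    technical_rule: str = "drop"  # {"drop", "keep"}
    artifact_rule: str = "none"  # key of ARTIFACT_KEEP_SETS
    artifact_scope: str = "both"  # {"async_only", "both"}
    zero_lt: str = "keep"  # {"drop", "keep"}
    sd_k: float | None = None  # {None, 2, 2.5, 3}
    min_trials: int | None = None  # {None, 2, 4, 8}
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.technical_rule not in ("drop", "keep"):
            raise ValueError("technical_rule must be 'drop' or 'keep'")
        if self.artifact_rule not in ARTIFACT_KEEP_SETS:
            raise ValueError(f"unknown artifact_rule {self.artifact_rule!r}")
        if self.artifact_scope not in ("async_only", "both"):
            raise ValueError("artifact_scope must be 'async_only' or 'both'")
        if self.zero_lt not in ("drop", "keep"):
            raise ValueError("zero_lt must be 'drop' or 'keep'")
        if self.sd_k is not None and self.sd_k <= 0:
            raise ValueError("sd_k must be positive or None")
        if self.min_trials is not None and self.min_trials < 1:
            raise ValueError("min_trials must be >= 1 or None")


def compute_looking_time(
    gaze: GazeStream, aoi: AOI, trial_window: tuple[float, float]
) -> float:
    """Looking time (ms) = number of valid in-AOI samples x sample period.

    The trial window is half-open ``[onset, offset)``; invalid samples never
    count toward the AOI dwell time.
    """
    t0, t1 = trial_window
    if t1 <= t0:
        raise ValueError("trial window must have positive length")
    m = (gaze.times_ms >= t0) & (gaze.times_ms < t1)
    if not np.any(m):
        raise InsufficientDataError("gaze stream does not cover the trial window")
    in_aoi = gaze.valid[m] & aoi.contains(gaze.x_px[m], gaze.y_px[m])
    period_ms = 1000.0 / gaze.fs_hz
    return float(np.count_nonzero(in_aoi) * period_ms)


def grade_cardiac_artifact(n_expected: int, n_detected: int) -> str:
    """Grade a cardiac trial by the fraction of R-peaks picked up."""
    if n_expected <= 0:
        raise ValueError("n_expected must be positive")
    if n_detected >= n_expected:
        return "none"
    frac = n_detected / n_expected
    return "small" if frac >= CARDIAC_PCT85 else "large"


def grade_resp_artifact(transient_overlap: float) -> str:
    """Grade a respiratory trial by the transient's overlap fraction with it."""
    if transient_overlap < 0 or transient_overlap > 1:
        raise ValueError("transient_overlap must lie in [0, 1]")
    if transient_overlap == 0:
        return "none"
    return "small" if transient_overlap < RESP_SMALL_OVERLAP else "large"


def flag_physio_artifacts(trial: dict, task: str) -> dict:
    """Flag one trial record from its physiological bookkeeping.

    For the cardiac task the record needs ``n_rpeaks_expected`` and
    ``n_rpeaks_detected``; for the respiratory task ``transient_overlap``
    (fraction of the trial covered by a flagged movement transient).  Missing
    physiology marks the trial as a technical error instead of guessing.
    Returns ``{"artifact_flag": ..., "technical_error": ...}``.
    """
    try:
        if task == "iBEATs":
            flag = grade_cardiac_artifact(
                int(trial["n_rpeaks_expected"]), int(trial["n_rpeaks_detected"])
            )
        elif task == "iBREATH":
            flag = grade_resp_artifact(float(trial["transient_overlap"]))
        else:
            raise ValueError(f"unknown task {task!r}")
    except (KeyError, TypeError):
        return {"artifact_flag": "none", "technical_error": True}
    return {"artifact_flag": flag, "technical_error": False}


def apply_exclusions(
    table: pd.DataFrame,
    policy: ExclusionPolicy,
    ledger: dict | None = None,
) -> pd.DataFrame:
    """Deterministic trial/infant filter: technical -> artifact -> zero-LT ->
    per-infant minimum trial count.

    SD-based outlier rejection is a separate step (:func:`reject_sd_outliers`);
    :func:`run_policy` composes the full chain.  If ``ledger`` is given, the
    number of rows removed at each step is recorded under that step's name.
    """
    out = table
    if ledger is None:
        ledger = {}
    ledger["rows_in"] = len(out)

    if policy.technical_rule == "drop":
        keep = ~out["technical_error"].astype(bool)
        ledger["technical"] = int((~keep).sum())
        out = out[keep]
    else:
        ledger["technical"] = 0

    keep_flags = ARTIFACT_KEEP_SETS[policy.artifact_rule]
    flag_ok = out["artifact_flag"].isin(keep_flags)
    if policy.artifact_scope == "async_only":
        keep = flag_ok | (out["condition"] == "sync")
    else:
        keep = flag_ok
    ledger["artifact"] = int((~keep).sum())
    out = out[keep]

    if policy.zero_lt == "drop":
        keep = out["looking_time_ms"] > 0
        ledger["zero_lt"] = int((~keep).sum())
        out = out[keep]
    else:
        ledger["zero_lt"] = 0

    if policy.min_trials is not None:
        counts = out.groupby("infant_id")["trial_index"].transform("count")
        keep = counts >= policy.min_trials
        ledger["min_trials"] = int((~keep).sum())
        out = out[keep]
    else:
        ledger["min_trials"] = 0

    ledger["rows_out"] = len(out)
    return out.copy()


def reject_sd_outliers(
    table: pd.DataFrame, k: float | None, ledger: dict | None = None
) -> pd.DataFrame:
    """Drop trials beyond ``k`` SDs of their condition's group mean (single pass).

    The mean and SD are computed at trial level across all infants within each
    condition.  ``k=None`` is the identity; a condition with fewer than two
    trials is left untouched.
    """
    if ledger is None:
        ledger = {}
    if k is None:
        ledger["sd_outlier"] = 0
        return table.copy()
    if k <= 0:
        raise ValueError("k must be positive or None")
    keep = pd.Series(True, index=table.index)
    for _, grp in table.groupby("condition"):
        if len(grp) < 2:
            continue
        lt = grp["looking_time_ms"]
        mean, sd = lt.mean(), lt.std(ddof=1)
        if sd == 0:
            continue
        keep.loc[grp.index] = (lt - mean).abs() <= k * sd
    ledger["sd_outlier"] = int((~keep).sum())
    return table[keep].copy()


def run_policy(
    table: pd.DataFrame, policy: ExclusionPolicy
) -> tuple[pd.DataFrame, dict]:
    """Full preprocessing chain for one policy, with an exclusion ledger.

    Order: technical -> artifact -> zero-LT -> SD outliers -> min-trials.  SD
    rejection runs before the minimum-trial criterion so that inclusion
    reflects the trials that are actually analyzable.
    """
    ledger: dict = {}
    base = ExclusionPolicy(
        technical_rule=policy.technical_rule,
        artifact_rule=policy.artifact_rule,
        artifact_scope=policy.artifact_scope,
        zero_lt=policy.zero_lt,
        sd_k=None,
        min_trials=None,
        log_transform=policy.log_transform,
    )
    out = apply_exclusions(table, base, ledger)
    out = reject_sd_outliers(out, policy.sd_k, ledger)
    if policy.min_trials is not None:
        counts = out.groupby("infant_id")["trial_index"].transform("count")
        keep = counts >= policy.min_trials
        ledger["min_trials"] = int((~keep).sum())
        out = out[keep].copy()
    ledger["rows_out"] = len(out)
    return out, ledger


def log_transform_lt(table: pd.DataFrame) -> pd.DataFrame:
    """Natural log of (looking time + 1 ms), applied before condition comparison."""
    out = table.copy()
    out["looking_time_ms"] = np.log(out["looking_time_ms"] + 1.0)
    return out


def subject_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Per-infant condition means and the absolute proportional score.

    Infants missing one of the two conditions are dropped (their id is listed
    in the frame's ``attrs["dropped"]``).  The score is
    ``|m_sync - m_async| / (m_sync + m_async)``, in [0, 1] whenever both
    means are positive.
    """
    rows = []
    dropped = []
    for (infant, age, task), grp in table.groupby(["infant_id", "age_group", "task"]):
        sync = grp.loc[grp["condition"] == "sync", "looking_time_ms"]
        asyn = grp.loc[grp["condition"] == "async", "looking_time_ms"]
        if sync.empty or asyn.empty:
            dropped.append(infant)
            continue
        m_s, m_a = float(sync.mean()), float(asyn.mean())
        total = m_s + m_a
        score = abs(m_s - m_a) / total if total > 0 else np.nan
        rows.append(
            {
                "infant_id": infant,
                "age_group": age,
                "task": task,
                "n_valid_sync": int(len(sync)),
                "n_valid_async": int(len(asyn)),
                "mean_lt_sync_ms": m_s,
                "mean_lt_async_ms": m_a,
                "discrimination_score": score,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "infant_id",
            "age_group",
            "task",
            "n_valid_sync",
            "n_valid_async",
            "mean_lt_sync_ms",
            "mean_lt_async_ms",
            "discrimination_score",
        ],
    )
    out.attrs["dropped"] = dropped
    return out
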