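"""Paired t, Cohen's d, TOST equivalence, and Spearman correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ibsense.exceptions import DegenerateDataError

__all__ = [
    "TestResult",
    "EquivalenceResult",
    "paired_t",
    "cohens_d_pooled",
    "tost",
    "spearman",
]


@dataclass(frozen=True)
class TestResult:
    """Two-tailed paired t-test result.

    ``cohens_d`` here is the paired-differences standardization
    (mean difference over the SD of the differences, d_z); the
    between-condition pooled d is :func:`cohens_d_pooled`.
    """

    t: float
    df: int
    p: float
    mean_diff_ms: float
    cohens_d: float
    n: int


@dataclass(frozen=True)
class EquivalenceResult:
    """TOST equivalence-test result against +/- d_bound * SD(diffs)."""

    d_bound: float
    t_tost: float
    df: int
    p_tost: float
    verdict: str  # {"equivalent", "inconclusive", "non-equivalent"}


def paired_t(diffs) -> TestResult:
    """Two-tailed one-sample t-test of paired differences against zero."""
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 3:
        raise DegenerateDataError("paired t needs at least 3 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("paired differences have zero variance")
    mean = d.mean()
    t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return TestResult(
        t=float(t),
        df=n - 1,
        p=float(p),
        mean_diff_ms=float(mean),
        cohens_d=float(mean / sd),
        n=n,
    )


def cohens_d_pooled(m1: float, s1: float, m2: float, s2: float) -> float:
    """Cohen's d with the root-mean-square of the two condition SDs.

    ``d = (m1 - m2) / sqrt((s1^2 + s2^2) / 2)`` — the standardizer that
    reproduces published condition-summary worked examples exactly.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("condition SDs must be positive")
    return float((m1 - m2) / np.sqrt((s1 * s1 + s2 * s2) / 2.0))


def tost(diffs, d_bound: float, alpha: float = 0.05) -> EquivalenceResult:
    """Two one-sided tests for equivalence within +/- d_bound * SD(diffs).

    The standardized bound is converted to a raw bound with the SD of the
    paired differences (d_z convention).  ``p_tost`` is the larger of the two
    one-sided p-values; the verdict is ``equivalent`` when ``p_tost < alpha``,
    ``non-equivalent`` when the (1 - 2*alpha) CI lies entirely outside the
    equivalence region, and ``inconclusive`` otherwise.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 3:
        raise DegenerateDataError("TOST needs at least 3 differences")
    if d_bound <= 0:
        raise ValueError("d_bound must be positive")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("paired differences have zero variance")
    mean = d.mean()
    se = sd / np.sqrt(n)
    df = n - 1
    bound = d_bound * sd
    t_lower = (mean + bound) / se  # H0: mean <= -bound
    t_upper = (mean - bound) / se  # H0: mean >= +bound
    p_lower = stats.t.sf(t_lower, df)
    p_upper = stats.t.cdf(t_upper, df)
    if p_lower >= p_upper:
        t_tost, p_tost = t_lower, p_lower
    else:
        t_tost, p_tost = t_upper, p_upper
    if p_tost < alpha:
        verdict = "equivalent"
    else:
        t_crit = stats.t.ppf(1 - alpha, df)
        lo, hi = mean - t_crit * se, mean + t_crit * se
        verdict = "non-equivalent" if (lo > bound or hi < -bound) else "inconclusive"
    return EquivalenceResult(
        d_bound=float(d_bound),
        t_tost=float(t_tost),
        df=df,
        p_tost=float(p_tost),
        verdict=verdict,
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties and t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("Spearman correlation needs at least 4 pairs")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
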