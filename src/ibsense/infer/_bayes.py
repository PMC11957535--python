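"""JZS Bayesian paired t-test and region-of-practical-equivalence summaries.

The Bayes factor follows the Jeffreys-Zellner-Siow setup for a one-sample
(paired) design: a Cauchy prior on the standardized effect delta with scale
``r`` (default sqrt(2)/2), so

    BF10 = [ integral T_df(t | nc = sqrt(n) * delta) dCauchy(delta; 0, r) ]
           / T_df(t | nc = 0)

evaluated by adaptive quadrature after the substitution ``delta = r tan(u)``
which maps the Cauchy measure to the uniform measure on (-pi/2, pi/2).
The posterior of delta (hence of the raw mean difference) is summarized from
a dense-grid inverse-CDF sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from ibsense.exceptions import DegenerateDataError

__all__ = ["BayesResult", "jzs_bf", "rope_pct", "hdi"]

DEFAULT_CAUCHY_SCALE = np.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class BayesResult:
    """JZS paired-t Bayes factor with posterior summaries on the ms scale."""

    bf10: float
    posterior_mean_diff: float
    hdi95: tuple[float, float]
    rope_bounds: tuple[float, float] | None
    pct_in_rope: float | None
    t: float
    df: int
    n: int
    posterior_samples: np.ndarray = field(repr=False, default=None)

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def _jzs_marginal_likelihood(t: float, df: int, n: int, r: float) -> float:
    """Marginal likelihood of t under the Cauchy(0, r) prior on delta."""

    def integrand(u: np.ndarray) -> np.ndarray:
        delta = r * np.tan(u)
        return stats.nct.pdf(t, df, np.sqrt(n) * delta) / np.pi

    val, err = integrate.quad(integrand, -np.pi / 2, np.pi / 2, limit=200)
    if not np.isfinite(val) or val <= 0 or (err > 1e-6 * max(val, 1e-300)):
        raise ArithmeticError(
            f"JZS quadrature did not converge (value={val!r}, abserr={err!r})"
        )
    return val


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m:] - s[: n - m]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m])


def jzs_bf(
    diffs,
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
    rope_bounds: tuple[float, float] | None = None,
    n_samples: int = 20_000,
    seed=0,
) -> BayesResult:
    """JZS Bayes factor and posterior for the mean of paired differences.

    ``rope_bounds`` (raw difference scale) trigger a ROPE percentage via
    :func:`rope_pct`.  Posterior samples of delta are drawn from a dense-grid
    inverse CDF and rescaled by the SD of the differences to the ms scale.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 3:
        raise DegenerateDataError("JZS test needs at least 3 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("paired differences have zero variance")
    if cauchy_scale <= 0:
        raise ValueError("cauchy_scale must be positive")
    mean = d.mean()
    t = mean / (sd / np.sqrt(n))
    df = n - 1

    marginal = _jzs_marginal_likelihood(float(t), df, n, float(cauchy_scale))
    null = stats.t.pdf(t, df)
    bf10 = float(marginal / null)

    # posterior of delta on a dense grid: prior x likelihood, inverse-CDF sample
    d_hat = t / np.sqrt(n)
    spread = np.sqrt(1.0 / n + d_hat**2 / (2 * df))
    lo = min(-8 * cauchy_scale, d_hat - 10 * spread)
    hi = max(8 * cauchy_scale, d_hat + 10 * spread)
    grid = np.linspace(lo, hi, 4001)
    log_post = stats.nct.logpdf(t, df, np.sqrt(n) * grid) + stats.cauchy.logpdf(
        grid, 0.0, cauchy_scale
    )
    post = np.exp(log_post - log_post.max())
    cdf = np.cumsum(post)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.random(n_samples)
    delta_samples = np.interp(u, cdf, grid)
    diff_samples = delta_samples * sd

    lo95, hi95 = hdi(diff_samples, 0.95)
    pct = None
    if rope_bounds is not None:
        pct = rope_pct(diff_samples, rope_bounds)
    return BayesResult(
        bf10=bf10,
        posterior_mean_diff=float(diff_samples.mean()),
        hdi95=(lo95, hi95),
        rope_bounds=rope_bounds,
        pct_in_rope=pct,
        t=float(t),
        df=df,
        n=n,
        posterior_samples=diff_samples,
    )


def rope_pct(posterior_samples, rope_bounds: tuple[float, float]) -> float:
    """Percentage of the 95% HDI mass inside the region of practical equivalence.

    Computed as the fraction of posterior samples that fall inside the HDI
    and also inside the ROPE, relative to all samples inside the HDI.
    """
    s = np.asarray(posterior_samples, dtype=float)
    if s.size < 1000:
        raise ValueError("ROPE summaries need at least 1000 posterior samples")
    if np.any(~np.isfinite(s)):
        raise DegenerateDataError("posterior samples contain non-finite values")
    lo_r, hi_r = rope_bounds
    if not lo_r < hi_r:
        raise ValueError("rope_bounds must be an increasing pair")
    if np.ptp(s) == 0:
        return 100.0 if lo_r <= s[0] <= hi_r else 0.0
    lo_h, hi_h = hdi(s, 0.95)
    in_hdi = (s >= lo_h) & (s <= hi_h)
    n_hdi = int(np.count_nonzero(in_hdi))
    if n_hdi == 0:
        raise DegenerateDataError("empty HDI; posterior is degenerate")
    in_both = in_hdi & (s >= lo_r) & (s <= hi_r)
    return float(100.0 * np.count_nonzero(in_both) / n_hdi)
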