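"""Beta-error mixed model with a participant random intercept.

The outcome y in (0, 1) follows a Beta distribution parametrized by its mean
``mu`` and precision ``phi`` (shape parameters ``mu*phi`` and
``(1-mu)*phi``); the mean is linked to the linear predictor by the logit, and
each group (participant) carries a Normal(0, sigma^2) random intercept.  The
marginal likelihood integrates the random intercept out by adaptive
Gauss-Hermite quadrature (default 15 nodes): per group the integrand's mode
and curvature are located by Newton steps and the Hermite nodes are centred
and scaled there.

Looking times are mapped into (0, 1) by dividing by the maximum trial
duration and applying the Smithson-Verkuilen squeeze
``(y * (n - 1) + 0.5) / n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ibsense.exceptions import ConfigurationError, DegenerateDataError

__all__ = [
    "BetaMixedModel",
    "BetaMixedModelResults",
    "fit_beta_glmm",
    "lrt_and_bic",
    "marginal_contrast",
    "condition_emm_contrast",
    "smithson_verkuilen_squeeze",
]

_MU_EPS = 1e-10


def smithson_verkuilen_squeeze(y: np.ndarray, n: int) -> np.ndarray:
    """Map [0, 1] data strictly into (0, 1): ``(y * (n - 1) + 0.5) / n``."""
    y = np.asarray(y, dtype=float)
    return (y * (n - 1) + 0.5) / n


def _obs_loglik(eta: np.ndarray, ylog: np.ndarray, y1log: np.ndarray, phi: float) -> np.ndarray:
    """Beta log-density per observation for linear predictor ``eta``."""
    mu = np.clip(special.expit(eta), _MU_EPS, 1 - _MU_EPS)
    a = mu * phi
    b = (1 - mu) * phi
    return (a - 1) * ylog + (b - 1) * y1log - special.betaln(a, b)


def _obs_score_hess(eta, ystar, phi):
    """First and second derivative of the beta log-density w.r.t. eta."""
    mu = np.clip(special.expit(eta), _MU_EPS, 1 - _MU_EPS)
    a = mu * phi
    b = (1 - mu) * phi
    w = mu * (1 - mu)
    mustar = special.psi(a) - special.psi(b)
    resid = ystar - mustar
    g1 = phi * w * resid
    trig = special.polygamma(1, a) + special.polygamma(1, b)
    g2 = phi * w * (1 - 2 * mu) * resid - (phi * w) ** 2 * trig
    return g1, g2


class BetaMixedModel:
    """Beta regression with logit mean link, constant precision, and a
    Normal random intercept per group, fitted by marginal ML.

    Parameters
    ----------
    endog : array, strictly inside (0, 1)
    exog : (n_obs, k) fixed-effects design matrix (must be full rank)
    groups : array of group labels (the random-intercept factor)
    exog_names : optional coefficient names
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if np.any(y <= 0) or np.any(y >= 1):
            raise ValueError(
                "endog must lie strictly in (0, 1); rescale and squeeze first"
            )
        if X.shape[0] != y.size:
            raise ValueError("endog and exog length mismatch")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effects design is not full rank")
        codes, uniques = pd.factorize(np.asarray(groups))
        self.endog = y
        self.exog = X
        self.group_codes = codes
        self.group_labels = uniques
        self.n_obs = y.size
        self.n_groups = len(uniques)
        self.k_fixed = X.shape[1]
        if exog_names is None:
            exog_names = [f"x{j}" for j in range(self.k_fixed)]
        self.exog_names = list(exog_names)
        self._ylog = np.log(y)
        self._y1log = np.log1p(-y)
        self._ystar = self._ylog - self._y1log
        self._b_cache = np.zeros(self.n_groups)

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, groups: str) -> "BetaMixedModel":
        """Build from a patsy formula; ``groups`` names the participant column."""
        import patsy

        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        return cls(
            endog=np.asarray(y).ravel(),
            exog=np.asarray(X),
            groups=data.loc[X.index, groups].to_numpy(),
            exog_names=list(X.columns),
        )

    # -- likelihood ---------------------------------------------------------

    def _group_modes(self, eta0, phi, sigma2, iters):
        """Vectorized Newton search for per-group modes of the integrand."""
        idx = self.group_codes
        b = self._b_cache.copy()
        h2 = np.full(self.n_groups, -1.0 / sigma2)
        for _ in range(iters):
            eta = eta0 + b[idx]
            g1, g2 = _obs_score_hess(eta, self._ystar, phi)
            h1 = np.bincount(idx, weights=g1, minlength=self.n_groups) - b / sigma2
            h2 = np.bincount(idx, weights=g2, minlength=self.n_groups) - 1.0 / sigma2
            h2 = np.minimum(h2, -1e-8)
            step = h1 / h2
            np.clip(step, -4.0, 4.0, out=step)
            b -= step
            if np.max(np.abs(step)) < 1e-11:
                break
        self._b_cache = b
        return b, h2

    def loglike(self, params, nodes: int = 15) -> float:
        """Marginal log-likelihood via adaptive Gauss-Hermite quadrature."""
        beta = params[: self.k_fixed]
        phi = float(np.exp(params[self.k_fixed]))
        sigma = float(np.exp(params[self.k_fixed + 1]))
        sigma2 = max(sigma * sigma, 1e-300)
        eta0 = self.exog @ beta
        idx = self.group_codes
        b_hat, h2 = self._group_modes(eta0, phi, sigma2, iters=50)
        s_hat = 1.0 / np.sqrt(-h2)
        x, w = np.polynomial.hermite.hermgauss(nodes)
        log_terms = np.empty((nodes, self.n_groups))
        log_prior_const = -0.5 * np.log(2 * np.pi) - np.log(sigma)
        for k in range(nodes):
            b_k = b_hat + np.sqrt(2.0) * s_hat * x[k]
            eta = eta0 + b_k[idx]
            obs = _obs_loglik(eta, self._ylog, self._y1log, phi)
            h = np.bincount(idx, weights=obs, minlength=self.n_groups)
            h += -0.5 * b_k * b_k / sigma2 + log_prior_const
            log_terms[k] = np.log(w[k]) + x[k] * x[k] + h
        ll_groups = special.logsumexp(log_terms, axis=0)
        ll_groups += 0.5 * np.log(2.0) + np.log(s_hat)
        return float(np.sum(ll_groups))

    def _loglike_fixed_only(self, params) -> float:
        """Plain beta-regression log-likelihood (random-intercept variance 0)."""
        beta = params[: self.k_fixed]
        phi = float(np.exp(params[self.k_fixed]))
        eta0 = self.exog @ beta
        return float(np.sum(_obs_loglik(eta0, self._ylog, self._y1log, phi)))

    def _start_params(self, fix_sigma):
        ystar = self._ystar
        beta0, *_ = np.linalg.lstsq(self.exog, ystar, rcond=None)
        mu = special.expit(self.exog @ beta0)
        resid = self.endog - mu
        v = max(float(np.var(resid)), 1e-6)
        phi0 = max(float(np.mean(mu * (1 - mu))) / v - 1.0, 1.5)
        start = list(beta0) + [np.log(phi0)]
        if fix_sigma is None:
            start.append(np.log(0.3))
        return np.asarray(start)

    def fit(
        self,
        nodes: int = 15,
        start_params=None,
        maxiter: int = 500,
        fix_sigma: float | None = None,
    ) -> "BetaMixedModelResults":
        """Maximize the marginal likelihood.

        ``fix_sigma=0`` collapses the model to a fixed-effects beta
        regression (the analytic limit of the quadrature), which is the
        cross-check path against an independent beta-regression fit.
        """
        if fix_sigma is not None and fix_sigma != 0:
            raise ConfigurationError("only fix_sigma=0 (no random effect) is supported")
        self._b_cache = np.zeros(self.n_groups)
        if start_params is None:
            start_params = self._start_params(fix_sigma)
        if fix_sigma == 0:
            neg = lambda p: -self._loglike_fixed_only(p)
        else:
            neg = lambda p: -self.loglike(p, nodes=nodes)
        # log-precision and log-random-SD are box-bounded so degenerate data
        # (e.g. constant outcomes, phi -> inf) walk to a cap instead of
        # derailing the line search
        bounds = [(None, None)] * self.k_fixed + [(-5.0, 12.0)]
        if fix_sigma is None:
            bounds.append((-8.0, 3.0))
        res = optimize.minimize(
            neg, start_params, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-8},
        )
        if not np.all(np.isfinite(res.x)):
            raise ArithmeticError(
                f"beta mixed model fit failed (gradient norm {np.linalg.norm(res.jac):.3g})"
            )
        params = res.x
        from statsmodels.tools.numdiff import approx_hess1

        hess = approx_hess1(params, neg)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        llf = -res.fun
        k_params = params.size
        if not bool(res.success):
            # ignore gradient components pinned at an active box bound
            free = np.array(
                [lo is None or not np.isclose(p, lo) for p, (lo, _hi) in zip(params, bounds)]
            ) & np.array(
                [hi is None or not np.isclose(p, hi) for p, (_lo, hi) in zip(params, bounds)]
            )
            if float(np.linalg.norm(res.jac[free])) > 1e-2:
                raise ArithmeticError(
                    f"beta mixed model did not converge (gradient norm "
                    f"{np.linalg.norm(res.jac):.3g})"
                )
        return BetaMixedModelResults(
            model=self,
            params=params,
            cov_params_full=cov,
            llf=llf,
            k_params=k_params,
            nodes=nodes,
            fixed_sigma=fix_sigma,
        )

    @staticmethod
    def simulate(exog, beta, phi, sigma, groups, rng) -> np.ndarray:
        """Draw outcomes from the generative model (for recovery studies)."""
        X = np.asarray(exog, dtype=float)
        codes, uniques = pd.factorize(np.asarray(groups))
        b = rng.normal(0.0, sigma, size=len(uniques))
        mu = np.clip(special.expit(X @ np.asarray(beta) + b[codes]), _MU_EPS, 1 - _MU_EPS)
        return rng.beta(mu * phi, (1 - mu) * phi)


@dataclass
class BetaMixedModelResults:
    """Fit results: coefficient table, precision, random-intercept SD, fit stats."""

    model: BetaMixedModel
    params: np.ndarray
    cov_params_full: np.ndarray
    llf: float
    k_params: int
    nodes: int
    fixed_sigma: float | None = None

    # -- parameter views ----------------------------------------------------

    @property
    def fe_params(self) -> np.ndarray:
        return self.params[: self.model.k_fixed]

    @property
    def precision_phi(self) -> float:
        return float(np.exp(self.params[self.model.k_fixed]))

    @property
    def random_intercept_sd(self) -> float:
        if self.fixed_sigma is not None:
            return float(self.fixed_sigma)
        return float(np.exp(self.params[self.model.k_fixed + 1]))

    @property
    def bse(self) -> np.ndarray:
        se = np.sqrt(np.maximum(np.diag(self.cov_params_full), 0.0))
        return se[: self.model.k_fixed]

    @property
    def zvalues(self) -> np.ndarray:
        return self.fe_params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def nobs(self) -> int:
        return self.model.n_obs

    @property
    def n_groups(self) -> int:
        return self.model.n_groups

    @property
    def bic(self) -> float:
        return float(-2 * self.llf + self.k_params * np.log(self.nobs))

    def cov_fe(self) -> np.ndarray:
        k = self.model.k_fixed
        return self.cov_params_full[:k, :k]

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.fe_params - z * self.bse
        hi = self.fe_params + z * self.bse
        return np.column_stack([lo, hi])

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.fe_params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.model.exog_names,
        )

    def summary(self) -> str:
        head = [
            "Beta-error mixed model (logit link, random intercept)",
            f"  n_obs: {self.nobs}   groups: {self.n_groups}   "
            f"quadrature nodes: {self.nodes}",
            f"  log-likelihood: {self.llf:.3f}   BIC: {self.bic:.3f}",
            f"  precision phi: {self.precision_phi:.3f}   "
            f"random-intercept SD: {self.random_intercept_sd:.4f}",
            "",
        ]
        table = self.coef_table().to_string(float_format=lambda v: f"{v: .4f}")
        return "\n".join(head) + table

    def to_dict(self) -> dict:
        return {
            "coefficients": [
                {
                    "name": n,
                    "estimate": float(e),
                    "se": float(s),
                    "z": float(z),
                    "p": float(p),
                }
                for n, e, s, z, p in zip(
                    self.model.exog_names, self.fe_params, self.bse,
                    self.zvalues, self.pvalues,
                )
            ],
            "random_intercept_sd": self.random_intercept_sd,
            "precision_phi": self.precision_phi,
            "loglik": float(self.llf),
            "bic": self.bic,
            "n_obs": self.nobs,
            "n_groups": self.n_groups,
        }


def fit_beta_glmm(
    table: pd.DataFrame,
    fixed_design: str,
    random_intercept_by: str,
    scaling: dict | None = None,
    nodes: int = 15,
) -> BetaMixedModelResults:
    """Fit the beta-error mixed model to a trial table.

    ``fixed_design`` is a patsy right-hand side (e.g.
    ``"condition * C(age_group)"``); the outcome column (default
    ``looking_time_ms``) is divided by ``scaling["max_ms"]`` and squeezed into
    (0, 1) before fitting.  Pass ``scaling={"outcome": col}`` with values
    already in (0, 1) (e.g. discrimination scores) to skip rescaling.
    """
    scaling = dict(scaling or {})
    outcome = scaling.get("outcome", "looking_time_ms")
    data = table.reset_index(drop=True).copy()
    y = data[outcome].to_numpy(dtype=float)
    if "max_ms" in scaling:
        y = y / float(scaling["max_ms"])
        if np.any(y < 0) or np.any(y > 1):
            raise ValueError("outcome exceeds the given maximum; scaling failed")
        y = smithson_verkuilen_squeeze(y, y.size)
    elif np.any(y <= 0) or np.any(y >= 1):
        y = smithson_verkuilen_squeeze(np.clip(y, 0, 1), y.size)
    data["_y"] = y
    model = BetaMixedModel.from_formula(f"_y ~ {fixed_design}", data, random_intercept_by)
    return model.fit(nodes=nodes)


def lrt_and_bic(
    full_fit: BetaMixedModelResults, null_fit: BetaMixedModelResults
) -> tuple[float, int, float, float]:
    """Likelihood-ratio test of nested fits plus the BIC difference.

    Returns ``(chi2, df, p, delta_bic)`` with ``delta_bic = bic_null -
    bic_full`` (positive favors the full model).
    """
    if full_fit.nobs != null_fit.nobs:
        raise ValueError("fits compare different data")
    if not set(null_fit.model.exog_names) <= set(full_fit.model.exog_names):
        raise ValueError("null model terms are not a subset of the full model")
    df = full_fit.k_params - null_fit.k_params
    if df < 0:
        raise ValueError("null model has more parameters than the full model")
    chi2 = max(0.0, 2.0 * (full_fit.llf - null_fit.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    delta_bic = null_fit.bic - full_fit.bic
    return float(chi2), int(df), p, float(delta_bic)


def condition_emm_contrast(
    exog_names: list[str], condition_term: str, interaction_terms: list[str]
) -> np.ndarray:
    """Contrast vector for the condition effect averaged over factor levels.

    With treatment coding, the marginal (estimated-marginal-means style)
    condition contrast averaged over a factor with ``m`` levels puts weight 1
    on the condition main effect and ``1/m`` on each condition-by-level
    interaction (the reference level contributes the main effect alone).
    """
    L = np.zeros(len(exog_names))
    if condition_term not in exog_names:
        raise ValueError(f"{condition_term!r} not among coefficients")
    L[exog_names.index(condition_term)] = 1.0
    m = len(interaction_terms) + 1
    for term in interaction_terms:
        if term not in exog_names:
            raise ValueError(f"{term!r} not among coefficients")
        L[exog_names.index(term)] = 1.0 / m
    return L


def marginal_contrast(
    fit: BetaMixedModelResults, contrast: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float], float, float]:
    """Odds ratio for a logit-scale contrast with a delta-method CI.

    Returns ``(odds_ratio, (ci_lo, ci_hi), t, p)`` using a t reference
    distribution with ``n_obs - k_fixed`` degrees of freedom.
    """
    L = np.asarray(contrast, dtype=float)
    if L.size != fit.model.k_fixed:
        raise ValueError("contrast length must match the fixed-effects design")
    est = float(L @ fit.fe_params)
    var = float(L @ fit.cov_fe() @ L)
    if var <= 0 or not np.isfinite(var):
        raise ValueError("contrast is not estimable from this fit")
    se = np.sqrt(var)
    df = fit.nobs - fit.model.k_fixed
    t = est / se
    p = float(2 * stats.t.sf(abs(t), df))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ci = (float(np.exp(est - tcrit * se)), float(np.exp(est + tcrit * se)))
    return float(np.exp(est)), ci, float(t), p
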