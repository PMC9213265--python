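"""Proportional-odds (cumulative-logit) ordinal regression.

The model for an ordered outcome Y in {0, 1, ..., K-1} with covariates x:

    P(Y >= k | x) = logistic(alpha_k + x' beta),   k = 1, ..., K-1,

with strictly decreasing cutpoints alpha_1 > ... > alpha_{K-1} (the
cumulative probabilities are nested) and a single beta shared across
cutpoints — the proportional-odds assumption.  With this orientation a
positive beta means higher odds of the more extreme outcome levels, so
exp(beta) is the cumulative odds ratio.

Fitting is a damped Newton iteration on the log-likelihood with an
analytic gradient; the observed information (for standard errors and the
Newton step) is a central finite difference of that gradient.  The
log-likelihood is guaranteed non-decreasing across iterations by step
halving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "ProportionalOddsModel",
    "ProportionalOddsResults",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when the Newton iteration fails (e.g. under separation).

    Carries the iteration trace (log-likelihood and gradient norm per
    iteration) in ``trace`` for diagnosis.
    """

    def __init__(self, message: str, trace: list[tuple[int, float, float]]):
        super().__init__(message + f" (last iterations: {trace[-3:]})")
        self.trace = trace


class ProportionalOddsModel:
    """Cumulative-logit model for an ordered categorical outcome.

    Parameters
    ----------
    endog : array of int in {0..K-1}
        Ordered outcome; all K levels must be present and K >= 3.
    exog : 2-D array
        Covariate matrix, no intercept column (cutpoints play that role),
        no constant columns.
    exog_names : optional list of column names.
    """

    def __init__(self, endog, exog=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=int)
        if exog is None or np.size(exog) == 0:
            self.exog = np.empty((len(self.endog), 0))
        else:
            self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
            if self.exog.shape[0] != self.endog.shape[0]:
                self.exog = self.exog.T
        levels = np.unique(self.endog)
        self.k_levels = int(self.endog.max()) + 1
        if self.k_levels < 3 or len(levels) != self.k_levels or self.endog.min() != 0:
            raise ValueError(
                "outcome must take every level 0..K-1 with K >= 3 "
                f"(observed levels {levels.tolist()})"
            )
        if self.exog.shape[1]:
            if np.any(np.ptp(self.exog, axis=0) == 0):
                raise ValueError("constant covariate column in exog")
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j + 1}" for j in range(self.exog.shape[1])]
        )
        self._ymat = np.eye(self.k_levels, dtype=bool)[self.endog]  # n x K indicator

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome: str, covariates: list[str]
    ) -> "ProportionalOddsModel":
        return cls(data[outcome].to_numpy(), data[list(covariates)].to_numpy(),
                   exog_names=list(covariates))

    # -- likelihood ----------------------------------------------------

    def _cumprobs(self, params: np.ndarray) -> np.ndarray:
        """n x (K+1) matrix of P(Y >= k), k = 0..K (1 and 0 at the ends)."""
        kk = self.k_levels - 1
        alphas, beta = params[:kk], params[kk:]
        eta = self.exog @ beta if beta.size else np.zeros(len(self.endog))
        g = np.empty((len(self.endog), self.k_levels + 1))
        g[:, 0] = 1.0
        g[:, -1] = 0.0
        for k in range(1, self.k_levels):
            g[:, k] = expit(alphas[k - 1] + eta)
        return g

    def loglike(self, params: np.ndarray) -> float:
        g = self._cumprobs(params)
        cellp = g[:, :-1] - g[:, 1:]  # P(Y = k)
        p_obs = cellp[self._ymat]
        if np.any(p_obs <= 0):
            return -np.inf
        return float(np.log(p_obs).sum())

    def score(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient of the log-likelihood."""
        kk = self.k_levels - 1
        g = self._cumprobs(params)
        cellp = np.clip(g[:, :-1] - g[:, 1:], 1e-300, None)
        p_obs = cellp[self._ymat]
        # d p_y / d eta_k: sigma'(eta_k) enters +ve for k == y, -ve for k == y+1
        sigp = g[:, 1:-1] * (1 - g[:, 1:-1])  # n x kk, sigma'(alpha_k + eta)
        y = self.endog
        d_eta = np.zeros((len(y), kk))
        for k in range(1, self.k_levels):  # cutpoint index k -> column k-1
            plus = y == k
            minus = y == k - 1
            d_eta[plus, k - 1] += sigp[plus, k - 1] / p_obs[plus]
            d_eta[minus, k - 1] -= sigp[minus, k - 1] / p_obs[minus]
        grad_alpha = d_eta.sum(axis=0)
        grad_beta = self.exog.T @ d_eta.sum(axis=1) if self.exog.shape[1] else np.empty(0)
        return np.concatenate([grad_alpha, grad_beta])

    def hessian(self, params: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
        """Observed information via central differences of the gradient."""
        p = params.size
        h = rel_step * np.maximum(1.0, np.abs(params))
        out = np.empty((p, p))
        for j in range(p):
            e = np.zeros(p)
            e[j] = h[j]
            out[:, j] = (self.score(params + e) - self.score(params - e)) / (2 * h[j])
        return (out + out.T) / 2.0

    def _start_params(self) -> np.ndarray:
        kk = self.k_levels - 1
        n = len(self.endog)
        cum = np.array([(self.endog >= k).mean() for k in range(1, self.k_levels)])
        cum = np.clip(cum, 0.5 / n, 1 - 0.5 / n)
        alphas = np.log(cum / (1 - cum))
        # enforce strictly decreasing start
        for k in range(1, kk):
            alphas[k] = min(alphas[k], alphas[k - 1] - 1e-6)
        return np.concatenate([alphas, np.zeros(self.exog.shape[1])])

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 200,
        gtol: float = 1e-6,
    ) -> "ProportionalOddsResults":
        """Damped Newton maximization of the cumulative-logit likelihood."""
        params = self._start_params() if start_params is None else np.asarray(
            start_params, dtype=float
        )
        ll = self.loglike(params)
        trace: list[tuple[int, float, float]] = []
        converged = False
        for it in range(maxiter):
            grad = self.score(params)
            gnorm = float(np.linalg.norm(grad))
            trace.append((it, ll, gnorm))
            if gnorm < gtol:
                converged = True
                break
            hess = self.hessian(params)
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = grad  # fall back to steepest ascent
            # step halving keeps the log-likelihood non-decreasing
            scale = 1.0
            for _ in range(40):
                cand = params + scale * step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            else:
                raise ConvergenceError("no ascent direction found", trace)
            params, ll = cand, ll_new
        else:
            grad = self.score(params)
            gnorm = float(np.linalg.norm(grad))
            trace.append((maxiter, ll, gnorm))
            converged = gnorm < gtol
        if not converged:
            raise ConvergenceError(
                "Newton iteration did not converge (possible separation)", trace
            )
        if np.any(np.abs(params) > 30):
            # |logit| > 30 means a fitted probability within 1e-13 of 0/1:
            # the likelihood has no interior maximum (separation)
            raise ConvergenceError("separation: estimates diverged", trace)
        hess = self.hessian(params)
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            cov = np.full((params.size, params.size), np.nan)
        return ProportionalOddsResults(self, params, cov, ll, trace)


@dataclass
class ProportionalOddsResults:
    """Estimates, Wald inference and diagnostics of a proportional-odds fit."""

    model: ProportionalOddsModel
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    trace: list = field(repr=False, default_factory=list)

    @property
    def k_cut(self) -> int:
        return self.model.k_levels - 1

    @property
    def intercepts(self) -> np.ndarray:
        return self.params[: self.k_cut]

    @property
    def beta(self) -> np.ndarray:
        return self.params[self.k_cut :]

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2 * stats.norm.sf(np.abs(z))

    @property
    def converged(self) -> bool:
        return True  # fit() raises on non-convergence

    @property
    def grad_norm(self) -> float:
        return self.trace[-1][2] if self.trace else np.nan

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Table-2-shaped frame: estimate, OR, 95% CI, p per variable."""
        ci = self.conf_int(alpha)
        names = [f"intercept_{k + 1}" for k in range(self.k_cut)] + list(
            self.model.exog_names
        )
        rows = []
        for i, name in enumerate(names):
            is_beta = i >= self.k_cut
            rows.append(
                {
                    "variable": name,
                    "estimate": self.params[i],
                    "se": self.bse[i],
                    "OR": np.exp(self.params[i]) if is_beta else np.nan,
                    "ci_low": np.exp(ci[i, 0]) if is_beta else ci[i, 0],
                    "ci_high": np.exp(ci[i, 1]) if is_beta else ci[i, 1],
                    "p": self.pvalues[i],
                }
            )
        return pd.DataFrame(rows)

    def plot_odds_ratios(self, ax=None):
        """Forest plot of odds ratios with 95% CIs (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * len(self.model.exog_names) + 1))
        tab = self.summary().iloc[self.k_cut :]
        y = np.arange(len(tab))[::-1]
        ax.errorbar(
            tab["OR"], y,
            xerr=[tab["OR"] - tab["ci_low"], tab["ci_high"] - tab["OR"]],
            fmt="o", capsize=3,
        )
        ax.axvline(1.0, color="grey", lw=0.8)
        ax.set_yticks(y)
        ax.set_yticklabels(tab["variable"])
        ax.set_xscale("log")
        ax.set_xlabel("odds ratio (95% CI)")
        return ax
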