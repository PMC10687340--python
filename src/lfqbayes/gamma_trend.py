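"""Single-trend gamma regression of the mean-variance relationship.

The sample SD ``s_i`` of each feature is modeled as gamma distributed with a
log-link regression of its mean on the feature's sample mean:

    s_i ~ Gamma(alpha, beta_i),   E[s_i] = exp(g0 + gy * ybar_i)

so ``beta_i = alpha / exp(g0 + gy*ybar_i)``.  The fitted trend provides a
per-measurement uncertainty multiplier ``u_ij = exp(g0 + gy*y_ij)`` and the
shape/rate hyperparameters of the gamma prior on the per-feature SD in the
decision model.  The shape is estimated as the inverse Pearson dispersion,
the convention of R's ``summary.glm``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .preprocess import PeptideStats

__all__ = ["GRFit", "SigmaPrior", "fit_gr", "predict_uncertainty_gr", "sigma_prior_gr", "nrmse"]


@dataclass
class GRFit:
    """Fitted gamma regression: intercept, slope, shape and goodness-of-fit."""

    gamma0: float
    gamma_ybar: float
    shape: float
    nrmse: float

    def predict(self, y: np.ndarray) -> np.ndarray:
        return predict_uncertainty_gr(self, y)


@dataclass
class SigmaPrior:
    """Gamma(shape=alpha, rate=beta_i) prior on the per-feature SD.

    By construction ``alpha / beta_i`` equals the trend's expected SD at the
    feature's sample mean.
    """

    alpha: float
    beta: np.ndarray


def fit_gr(stats: PeptideStats) -> GRFit:
    """Fit the gamma GLM of SD on mean by IRLS.

    Requires at least 3 features with positive SD and a non-degenerate
    spread of sample means.
    """
    ok = stats.ok
    s = stats.s[ok]
    ybar = stats.ybar[ok]
    if s.size < 3:
        raise ValueError("need >= 3 features with positive SD")
    if (s <= 0).any():
        raise ValueError("sample SDs must be positive")
    if np.ptp(ybar) == 0:
        raise ValueError("degenerate covariate: sample means are constant")
    X = sm.add_constant(ybar)
    model = sm.GLM(s, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    try:
        res = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # pragma: no cover - statsmodels wraps failures
        raise RuntimeError(f"gamma GLM did not converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError(f"gamma GLM did not converge in {res.fit_history['iteration']} iterations")
    g0, gy = res.params
    shape = res.df_resid / res.pearson_chi2  # inverse Pearson dispersion
    s_hat = np.exp(g0 + gy * ybar)
    return GRFit(gamma0=float(g0), gamma_ybar=float(gy), shape=float(shape), nrmse=nrmse(s, s_hat))


def predict_uncertainty_gr(fit: GRFit, y: np.ndarray) -> np.ndarray:
    """Expected SD of the trend at abundance ``y``: ``exp(g0 + gy*y)``."""
    return np.exp(fit.gamma0 + fit.gamma_ybar * np.asarray(y, dtype=float))


def sigma_prior_gr(fit: GRFit, stats: PeptideStats) -> SigmaPrior:
    """Gamma prior hyperparameters with prior mean equal to the trend at ybar."""
    mu = predict_uncertainty_gr(fit, stats.ybar)
    return SigmaPrior(alpha=fit.shape, beta=fit.shape / mu)


def nrmse(s: np.ndarray, s_hat: np.ndarray) -> float:
    """Root-mean-square error normalized by the SD vector's variance (n-1)."""
    s = np.asarray(s, dtype=float)
    s_hat = np.asarray(s_hat, dtype=float)
    if s.shape != s_hat.shape or s.size < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    v = s.var(ddof=1)
    if v == 0:
        raise ValueError("Var(s) is zero; NRMSE undefined")
    return float(np.sqrt(np.mean((s - s_hat) ** 2) / v))
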