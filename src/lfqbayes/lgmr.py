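"""Latent gamma mixture regression (LGMR) of the mean-variance trend.

Each feature's sample SD is gamma distributed with a mean that mixes a
common exponentially decaying trend with a latent trend, weighted by a
per-feature mixing proportion theta in [0, 1]:

    s_i ~ Gamma(alpha, alpha / mu_i)
    mu_i = exp(g0 - gy * f(ybar_i)) + kappa * exp(theta_i * (g0L - gyL * f(ybar_i)))
    f(x) = (x - mean(ybar)) / sd(ybar)

Slopes gy, gyL are constrained non-negative so the trend never increases
with abundance; kappa is a small constant bounding the latent trend's
minimal contribution.  Priors: alpha ~ Half-Cauchy(25), g0 ~ N(0, 1),
g0L ~ Skew-Normal (right-skewed, weak), slopes ~ Half-Normal, theta_i ~
U(0, 1).  Inference is by NUTS on the unconstrained scale; posterior means
serve as point estimates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from . import mcmc
from .gamma_trend import SigmaPrior, nrmse
from .preprocess import PeptideStats

__all__ = [
    "LGMRConfig",
    "Standardizer",
    "LGMRPosterior",
    "fit_lgmr",
    "predict_uncertainty_lgmr",
    "sigma_prior_lgmr",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass
class LGMRConfig:
    """Sampler settings and prior hyperparameters for the mixture regression."""

    kappa: float = 0.001
    chains: int = 5
    warmup: int = 500
    draws: int = 2000
    adapt_delta: float = 0.9
    seed: int = 0
    slope_scale: float = 1.0  # Half-Normal scale of both slopes
    latent_loc: float = 1.0  # Skew-Normal location of the latent intercept
    latent_scale: float = 15.0
    latent_shape: float = 30.0
    alpha_scale: float = 25.0  # Half-Cauchy scale of the gamma shape
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.draws < 1:
            raise ValueError("draws must be >= 1")


@dataclass
class Standardizer:
    """Frozen location/scale of the fitting-stage sample means."""

    mu_ybar: float
    sd_ybar: float

    def __post_init__(self) -> None:
        if self.sd_ybar <= 0:
            raise ValueError("sd_ybar must be positive")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mu_ybar) / self.sd_ybar


@dataclass
class LGMRPosterior:
    """Posterior draws, point estimates and diagnostics of the LGMR fit.

    Scalar-parameter draws have shape ``(chains, draws)``; ``theta`` has
    shape ``(chains, draws, p)`` aligned with ``feature_ids``.
    """

    feature_ids: list[str]
    alpha: np.ndarray
    gamma0: np.ndarray
    gamma0L: np.ndarray
    gamma_ybar: np.ndarray
    gamma_ybarL: np.ndarray
    theta: np.ndarray
    standardizer: Standardizer
    kappa: float
    nrmse: float  # posterior mean of the per-draw NRMSE
    summaries: dict[str, dict[str, float]]
    divergence_fraction: float
    warnings: list[str] = field(default_factory=list)

    @property
    def means(self) -> dict[str, float]:
        return {
            name: float(getattr(self, name).mean())
            for name in ("alpha", "gamma0", "gamma0L", "gamma_ybar", "gamma_ybarL")
        }

    @property
    def theta_mean(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1]).mean(axis=0)

    def predict(self, feature_theta: float, y: np.ndarray) -> np.ndarray:
        return predict_uncertainty_lgmr(self, self.standardizer, feature_theta, y)

    def draws_frame(self, include_theta: bool = False) -> "object":
        """Posterior draws as a tidy table (one row per chain x draw).

        Scalar parameters always; per-feature ``theta`` columns on request.
        Suitable for writing to CSV/TSV/parquet.
        """
        import pandas as pd

        chains, draws = self.alpha.shape
        data = {
            "chain": np.repeat(np.arange(chains), draws),
            "draw": np.tile(np.arange(draws), chains),
        }
        for name in ("alpha", "gamma0", "gamma0L", "gamma_ybar", "gamma_ybarL"):
            data[name] = getattr(self, name).reshape(-1)
        df = pd.DataFrame(data)
        if include_theta:
            theta = self.theta.reshape(-1, self.theta.shape[-1])
            for j, fid in enumerate(self.feature_ids):
                df[f"theta[{fid}]"] = theta[:, j]
        return df

    def report(self) -> dict:
        """Fit report: point estimates, NRMSE and convergence diagnostics."""
        return {
            **self.means,
            "nrmse": self.nrmse,
            "divergence_fraction": self.divergence_fraction,
            "diagnostics": self.summaries,
            "warnings": list(self.warnings),
        }


def _mixture_mean(
    f: np.ndarray,
    theta: np.ndarray | float,
    g0: float,
    g0L: float,
    gy: float,
    gyL: float,
    kappa: float,
) -> np.ndarray:
    common = np.exp(g0 - gy * f)
    latent = kappa * np.exp(theta * (g0L - gyL * f))
    return common + latent


def _make_logp_grad(s: np.ndarray, f: np.ndarray, cfg: LGMRConfig):
    """Log joint density and gradient on the unconstrained scale.

    Parameter vector: [log alpha, g0, g0L, log gy, log gyL, logit theta_1..p].
    """
    p = s.size
    log_s = np.log(s)
    sum_log_s = float(log_s.sum())
    a_sc2 = cfg.alpha_scale**2
    w_loc, w_sc, w_sh = cfg.latent_loc, cfg.latent_scale, cfg.latent_shape
    tau2 = cfg.slope_scale**2
    kappa = cfg.kappa

    def logp_grad(z: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _logp_grad_impl(z)

    def _logp_grad_impl(z: np.ndarray) -> tuple[float, np.ndarray]:
        a, g0, g0L, by, byL = z[0], z[1], z[2], z[3], z[4]
        t = z[5:]
        alpha = np.exp(a)
        gy = np.exp(by)
        gyL = np.exp(byL)
        theta = special.expit(t)

        A = np.exp(g0 - gy * f)
        B = kappa * np.exp(theta * (g0L - gyL * f))
        mu = A + B
        if not (np.isfinite(alpha) and np.all(np.isfinite(mu))):
            return -np.inf, np.zeros(5 + p)

        # gamma likelihood with rate alpha/mu
        log_mu = np.log(mu)
        s_over_mu = s / mu
        ll = (
            p * (alpha * a - special.gammaln(alpha))
            - alpha * log_mu.sum()
            + (alpha - 1.0) * sum_log_s
            - alpha * s_over_mu.sum()
        )

        w = alpha * (s - mu) / mu**2  # d ll / d mu_i

        # priors + jacobians; alpha ~ Half-Cauchy(scale), jacobian a
        lp = ll - np.log1p(alpha**2 / a_sc2) + a
        # g0 ~ N(0,1)
        lp += -0.5 * g0**2
        # g0L ~ Skew-Normal(loc, scale, shape)
        tsn = (g0L - w_loc) / w_sc
        log_cdf = special.log_ndtr(w_sh * tsn)
        lp += -0.5 * tsn**2 + log_cdf
        # slopes ~ Half-Normal(tau), jacobians
        lp += -0.5 * (gy**2 + gyL**2) / tau2 + by + byL
        # theta ~ U(0,1); logit jacobian log(theta (1-theta))
        lp += float(np.sum(np.log(theta) + np.log1p(-theta)))

        grad = np.empty(5 + p)
        # d/da: likelihood term times alpha, plus prior terms
        dll_dalpha = (
            p * (a + 1.0 - special.digamma(alpha)) - log_mu.sum() + sum_log_s - s_over_mu.sum()
        )
        grad[0] = alpha * dll_dalpha - 2.0 * alpha**2 / (a_sc2 + alpha**2) + 1.0
        grad[1] = float(np.dot(w, A)) - g0
        # phi(x)/Phi(x) computed stably in log space
        ratio = np.exp(-0.5 * (w_sh * tsn) ** 2 - np.log(_SQRT_2PI) - log_cdf)
        grad[2] = float(np.dot(w, theta * B)) - tsn / w_sc + w_sh * ratio / w_sc
        grad[3] = gy * float(np.dot(w, -f * A)) - gy**2 / tau2 + 1.0
        grad[4] = gyL * float(np.dot(w, -theta * f * B)) - gyL**2 / tau2 + 1.0
        grad[5:] = w * (g0L - gyL * f) * B * theta * (1.0 - theta) + (1.0 - 2.0 * theta)
        return float(lp), grad

    return logp_grad


def fit_lgmr(stats: PeptideStats, cfg: LGMRConfig | None = None) -> LGMRPosterior:
    """Sample the LGMR posterior with NUTS and summarize it.

    Requires at least 10 features with positive SD.  Records a warning (not
    an error) if the divergent-transition fraction exceeds 1% or any scalar
    parameter's R-hat exceeds 1.05.
    """
    cfg = cfg or LGMRConfig()
    ok = stats.ok
    s = stats.s[ok]
    ybar = stats.ybar[ok]
    ids = [fid for fid, keep in zip(stats.feature_ids, ok) if keep]
    p = s.size
    if p < 10:
        raise ValueError("need >= 10 features with positive SD")
    std = Standardizer(mu_ybar=float(ybar.mean()), sd_ybar=float(ybar.std(ddof=1)))
    f = std(ybar)
    logp_grad = _make_logp_grad(s, f, cfg)

    med_log_s = float(np.log(np.median(s)))

    def init(rng: np.random.Generator) -> np.ndarray:
        z = np.zeros(5 + p)
        z[0] = np.log(2.0) + 0.2 * rng.standard_normal()
        z[1] = med_log_s + 0.2 * rng.standard_normal()
        z[2] = 1.0 + 0.5 * rng.standard_normal()
        z[3] = np.log(0.2) + 0.2 * rng.standard_normal()
        z[4] = np.log(0.2) + 0.2 * rng.standard_normal()
        z[5:] = 0.2 * rng.standard_normal(p)
        return z

    draws, chain_results = mcmc.run_nuts(
        logp_grad,
        init,
        chains=cfg.chains,
        n_warmup=cfg.warmup,
        n_draws=cfg.draws,
        seed=cfg.seed,
        target_accept=cfg.adapt_delta,
        max_treedepth=cfg.max_treedepth,
    )

    alpha = np.exp(draws[:, :, 0])
    gamma0 = draws[:, :, 1]
    gamma0L = draws[:, :, 2]
    gamma_ybar = np.exp(draws[:, :, 3])
    gamma_ybarL = np.exp(draws[:, :, 4])
    theta = special.expit(draws[:, :, 5:])

    # posterior-mean NRMSE: Eq-style goodness-of-fit with s_hat = mu per draw
    var_s = s.var(ddof=1)
    nr = 0.0
    n_total = cfg.chains * cfg.draws
    for c in range(cfg.chains):
        mu_c = _mixture_mean(
            f[None, :],
            theta[c],
            gamma0[c][:, None],
            gamma0L[c][:, None],
            gamma_ybar[c][:, None],
            gamma_ybarL[c][:, None],
            cfg.kappa,
        )
        nr += np.sqrt(np.mean((s[None, :] - mu_c) ** 2, axis=1) / var_s).sum()
    nrmse_mean = float(nr / n_total)

    summaries = {
        name: mcmc.summarize_draws(vals)
        for name, vals in (
            ("alpha", alpha),
            ("gamma0", gamma0),
            ("gamma0L", gamma0L),
            ("gamma_ybar", gamma_ybar),
            ("gamma_ybarL", gamma_ybarL),
        )
    }
    n_div = sum(r.n_divergent for r in chain_results)
    div_frac = n_div / n_total
    warnings: list[str] = []
    if div_frac > 0.01:
        warnings.append(f"divergent transitions: {100 * div_frac:.1f}% of draws")
    bad_rhat = {k: v["rhat"] for k, v in summaries.items() if v["rhat"] > 1.05}
    if bad_rhat:
        warnings.append(f"R-hat > 1.05 for {sorted(bad_rhat)}")

    return LGMRPosterior(
        feature_ids=ids,
        alpha=alpha,
        gamma0=gamma0,
        gamma0L=gamma0L,
        gamma_ybar=gamma_ybar,
        gamma_ybarL=gamma_ybarL,
        theta=theta,
        standardizer=std,
        kappa=cfg.kappa,
        nrmse=nrmse_mean,
        summaries=summaries,
        divergence_fraction=div_frac,
        warnings=warnings,
    )


def predict_uncertainty_lgmr(
    post: LGMRPosterior,
    std: Standardizer,
    feature_theta: float | np.ndarray,
    y: np.ndarray,
) -> np.ndarray:
    """Expected SD of the mixture trend at abundance ``y``, posterior means.

    ``feature_theta`` is the feature's (posterior-mean) latent mixing weight;
    the standardizer is the one frozen at fit time, also when ``y`` is an
    individual measurement.
    """
    feature_theta = np.asarray(feature_theta, dtype=float)
    if np.any(feature_theta < 0) or np.any(feature_theta > 1):
        raise ValueError("feature_theta must lie in [0, 1]")
    m = post.means
    return _mixture_mean(
        std(y),
        feature_theta,
        m["gamma0"],
        m["gamma0L"],
        m["gamma_ybar"],
        m["gamma_ybarL"],
        post.kappa,
    )


def sigma_prior_lgmr(post: LGMRPosterior, stats: PeptideStats) -> SigmaPrior:
    """Gamma prior on the per-feature SD with mean given by the mixture trend.

    ``stats`` must be the statistics the model was fitted on (feature order
    must match the posterior's ``theta``).
    """
    idx = {fid: i for i, fid in enumerate(stats.feature_ids)}
    order = [idx[fid] for fid in post.feature_ids]
    ybar = stats.ybar[order]
    mu = predict_uncertainty_lgmr(post, post.standardizer, post.theta_mean, ybar)
    alpha = post.means["alpha"]
    return SigmaPrior(alpha=alpha, beta=alpha / mu)
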