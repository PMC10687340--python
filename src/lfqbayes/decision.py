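"""Per-feature Bayesian hierarchical decision model.

Each feature (peptide, protein, PTM site) is modeled independently:

    y_n   ~ N((X mu)_n, sigma * u_n)          measurements, log2 scale
    mu_c  ~ N(mu0_c + eta_c * sigma, sigma)   condition means, expanded
    eta_c ~ N(0, 1)                           non-centered group effect
    sigma ~ Gamma(alpha, beta)                trend-derived prior
    mu0_c ~ N(ybar_c, sigma*sqrt(2/n_c))      empirical-Bayes prior, or
    mu0_c ~ N(0, 10)                          weakly informative prior

``u_n`` is the trend-predicted uncertainty multiplier of measurement ``n``.
For each contrast column ``k_m`` of K the decision statistic

    D_m ~ N(mu' k_m, sigma * g(xi_m)),   xi_m = sum_c |k_cm| / n_c

is drawn per posterior draw (``g`` is the identity by default, the square
root by option), and the probability of error is the two-sided tail mass
2*Phi(-|mean(D) - mu_h0| / sd(D)) from the posterior draws of D.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import special

from . import mcmc
from .gamma_trend import GRFit, SigmaPrior, predict_uncertainty_gr, sigma_prior_gr
from .lgmr import LGMRPosterior, predict_uncertainty_lgmr, sigma_prior_lgmr
from .preprocess import NormalizedMatrix, PeptideStats, summarize_peptides

__all__ = [
    "DesignMatrix",
    "ContrastSpec",
    "PeptideModelInput",
    "DecisionConfig",
    "DecisionResult",
    "design_from_conditions",
    "validate_contrasts",
    "build_mean_prior",
    "sample_peptide",
    "p_error",
    "run_all",
]


@dataclass
class DesignMatrix:
    """0/1 condition-indicator matrix with replicate counts per condition."""

    X: np.ndarray  # (N, C)
    n: np.ndarray  # (C,)
    condition_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not np.all(self.X.sum(axis=1) == 1) or not np.isin(self.X, (0, 1)).all():
            raise ValueError("each design row must have exactly one 1")
        if (self.n < 2).any():
            raise ValueError("every condition needs at least 2 replicates")
        if not np.array_equal(self.X.sum(axis=0).astype(int), self.n):
            raise ValueError("column sums of X must equal replicate counts")

    @property
    def condition_index(self) -> np.ndarray:
        return self.X.argmax(axis=1)


def design_from_conditions(conditions: list[str]) -> DesignMatrix:
    """Design matrix from a per-sample condition label list."""
    names = list(dict.fromkeys(conditions))
    idx = np.array([names.index(c) for c in conditions])
    X = np.zeros((len(conditions), len(names)))
    X[np.arange(len(conditions)), idx] = 1.0
    return DesignMatrix(X=X, n=X.sum(axis=0).astype(int), condition_names=names)


@dataclass
class ContrastSpec:
    """Validated contrast matrix K (C x M) with weighted sample sizes xi."""

    K: np.ndarray
    xi: np.ndarray


@dataclass
class PeptideModelInput:
    """Data and hyperparameters for one feature's decision model."""

    y: np.ndarray  # (N,) log2 measurements
    u: np.ndarray  # (N,) positive uncertainty multipliers
    alpha: float
    beta: float
    ybar_c: np.ndarray  # (C,) condition sample means


@dataclass
class DecisionConfig:
    """Sampler and decision settings for the per-feature model."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    adapt_delta: float = 0.8
    seed: int = 0
    scale_map: str = "xi"  # "xi" (literal) or "sqrt_xi" (sampling-theory SE)
    mu_h0: float | np.ndarray = 0.0
    max_treedepth: int = 10
    workers: int = 1


@dataclass
class DecisionResult:
    """Posterior summaries plus per-contrast log fold change and error probability."""

    feature_id: str
    summaries: dict[str, dict[str, float]]
    lfc: np.ndarray  # (M,) posterior mean of D
    err: np.ndarray  # (M,) error probabilities
    flagged: bool = False
    message: str = ""


def validate_contrasts(K_raw: np.ndarray, n: np.ndarray, tol: float = 1e-9) -> ContrastSpec:
    """Check contrast-column constraints and compute xi_m = sum_c |k_cm| / n_c.

    Each column must sum to zero, have absolute sum two, and its positive
    entries must sum to one.
    """
    K = np.atleast_2d(np.asarray(K_raw, dtype=float))
    n = np.asarray(n, dtype=float)
    if K.shape[0] != n.size:
        raise ValueError(f"K has {K.shape[0]} rows but there are {n.size} conditions")
    if K.shape[1] == 0:
        raise ValueError("no contrasts")
    for m in range(K.shape[1]):
        col = K[:, m]
        if abs(col.sum()) > tol:
            raise ValueError(f"contrast column {m}: sum {col.sum():g} != 0")
        if abs(np.abs(col).sum() - 2.0) > tol:
            raise ValueError(f"contrast column {m}: absolute sum {np.abs(col).sum():g} != 2")
        pos = col[col > 0].sum()
        if abs(pos - 1.0) > tol:
            raise ValueError(f"contrast column {m}: positive entries sum to {pos:g} != 1")
    xi = (np.abs(K) / n[:, None]).sum(axis=0)
    return ContrastSpec(K=K, xi=xi)


def build_mean_prior(kind: str, ybar_c: np.ndarray, n: np.ndarray) -> dict:
    """Parameters of the prior on the latent condition-mean center mu0.

    EB: mu0_c ~ N(ybar_c, sigma*sqrt(2/n_c)) — data-centered with variance
    twice the common variance over the replicate count.  WI: mu0_c ~ N(0, 10).
    """
    kind = kind.lower()
    if kind == "eb":
        return {"kind": "eb", "center": np.asarray(ybar_c, dtype=float),
                "sd_mult": np.sqrt(2.0 / np.asarray(n, dtype=float))}
    if kind == "wi":
        C = len(ybar_c)
        return {"kind": "wi", "center": np.zeros(C), "sd": 10.0}
    raise ValueError(f"unknown mean prior {kind!r} (use 'eb' or 'wi')")


@njit(cache=True)
def _decision_kernel(
    z: np.ndarray,
    y: np.ndarray,
    inv_u2: np.ndarray,
    cond: np.ndarray,
    C: int,
    alpha: float,
    beta: float,
    eb: bool,
    center: np.ndarray,
    sd_mult: np.ndarray,
    wi_sd: float,
) -> tuple[float, np.ndarray]:
    """Log joint and gradient; unconstrained z = [z_mu, eta, t0, log sigma]."""
    N = y.size
    dim = 3 * C + 1
    grad = np.zeros(dim)
    a = z[3 * C]
    sigma = np.exp(a)
    if not np.isfinite(sigma) or sigma <= 0.0:
        return -np.inf, grad
    inv_s2 = 1.0 / (sigma * sigma)

    mu = np.empty(C)
    dmu0_dt0 = np.empty(C)
    for c in range(C):
        z_mu, eta, t0 = z[c], z[C + c], z[2 * C + c]
        if eb:
            mu0 = center[c] + sigma * sd_mult[c] * t0
            dmu0_dt0[c] = sigma * sd_mult[c]
        else:
            mu0 = center[c] + wi_sd * t0
            dmu0_dt0[c] = wi_sd
        mu[c] = mu0 + sigma * (eta + z_mu)

    r2_sum = 0.0
    e_c = np.zeros(C)
    for n in range(N):
        resid = y[n] - mu[cond[n]]
        r2_sum += resid * resid * inv_u2[n]
        e_c[cond[n]] += resid * inv_u2[n]
    e_c *= inv_s2

    # -sum(log u) dropped (constant in z)
    lp = -N * a - 0.5 * r2_sum * inv_s2 + alpha * a - beta * sigma
    acc = 0.0
    for c in range(C):
        z_mu, eta, t0 = z[c], z[C + c], z[2 * C + c]
        lp -= 0.5 * (z_mu * z_mu + eta * eta + t0 * t0)
        grad[c] = sigma * e_c[c] - z_mu
        grad[C + c] = sigma * e_c[c] - eta
        grad[2 * C + c] = dmu0_dt0[c] * e_c[c] - t0
        dmu_dsigma = eta + z_mu + (sd_mult[c] * t0 if eb else 0.0)
        acc += e_c[c] * dmu_dsigma
    grad[3 * C] = -N + r2_sum * inv_s2 + sigma * acc + alpha - beta * sigma
    return lp, grad


def _make_logp_grad(inp: PeptideModelInput, design: DesignMatrix, prior: dict):
    """Bind one feature's data into the jitted decision-model kernel."""
    y = np.ascontiguousarray(inp.y, dtype=float)
    inv_u2 = np.ascontiguousarray(1.0 / inp.u**2, dtype=float)
    cond = np.ascontiguousarray(design.condition_index, dtype=np.int64)
    C = int(design.n.size)
    alpha, beta = float(inp.alpha), float(inp.beta)
    eb = prior["kind"] == "eb"
    center = np.ascontiguousarray(prior["center"], dtype=float)
    sd_mult = np.ascontiguousarray(prior["sd_mult"] if eb else np.zeros(C), dtype=float)
    wi_sd = float(prior.get("sd", 10.0))

    def logp_grad(z: np.ndarray) -> tuple[float, np.ndarray]:
        return _decision_kernel(z, y, inv_u2, cond, C, alpha, beta, eb, center, sd_mult, wi_sd)

    return logp_grad


def p_error(mu_D: float, sd_D: float, mu_h0: float = 0.0) -> float:
    """Two-sided tail mass of the decision statistic: 2*Phi(-|mu_D - mu_h0|/sd_D)."""
    if sd_D <= 0:
        raise ValueError("sd_D must be positive")
    return float(2.0 * special.ndtr(-abs(mu_D - mu_h0) / sd_D))


def sample_peptide(
    inp: PeptideModelInput,
    design: DesignMatrix,
    contrasts: ContrastSpec,
    prior: str = "eb",
    cfg: DecisionConfig | None = None,
    feature_id: str = "",
) -> DecisionResult:
    """NUTS inference of one feature's model and its decision statistics."""
    cfg = cfg or DecisionConfig()
    if inp.alpha <= 0 or inp.beta <= 0:
        raise ValueError("sigma prior parameters must be positive")
    if (inp.u <= 0).any():
        raise ValueError("uncertainties must be positive")
    C = design.n.size
    prior_params = build_mean_prior(prior, inp.ybar_c, design.n)
    logp_grad = _make_logp_grad(inp, design, prior_params)

    pooled_sd = max(float(inp.y.std(ddof=1)), 1e-3)

    def init(rng: np.random.Generator) -> np.ndarray:
        z = 0.1 * rng.standard_normal(3 * C + 1)
        z[3 * C] = np.log(pooled_sd) + 0.1 * rng.standard_normal()
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

    sigma = np.exp(draws[:, :, 3 * C])
    if prior_params["kind"] == "eb":
        mu0 = prior_params["center"] + sigma[:, :, None] * prior_params["sd_mult"] * draws[:, :, 2 * C : 3 * C]
    else:
        mu0 = prior_params["center"] + prior_params["sd"] * draws[:, :, 2 * C : 3 * C]
    mu = mu0 + sigma[:, :, None] * (draws[:, :, C : 2 * C] + draws[:, :, :C])

    # decision statistic, drawn once per posterior draw
    xi_scale = contrasts.xi if cfg.scale_map == "xi" else np.sqrt(contrasts.xi)
    rng_d = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(997,)))
    mean_D = mu @ contrasts.K  # (chains, draws, M)
    D = mean_D + sigma[:, :, None] * xi_scale * rng_d.standard_normal(mean_D.shape)

    M = contrasts.K.shape[1]
    mu_h0 = np.broadcast_to(np.asarray(cfg.mu_h0, dtype=float), (M,))
    summaries = {f"mu[{design.condition_names[c]}]": mcmc.summarize_draws(mu[:, :, c]) for c in range(C)}
    summaries["sigma"] = mcmc.summarize_draws(sigma)
    lfc = np.empty(M)
    err = np.empty(M)
    for m in range(M):
        summaries[f"D[{m}]"] = mcmc.summarize_draws(D[:, :, m])
        flat = D[:, :, m].reshape(-1)
        lfc[m] = flat.mean()
        err[m] = p_error(lfc[m], flat.std(ddof=1), float(mu_h0[m]))

    flagged = summaries["sigma"]["rhat"] > 1.05 or any(
        summaries[f"D[{m}]"]["rhat"] > 1.05 for m in range(M)
    )
    message = "rhat>1.05" if flagged else ""
    return DecisionResult(
        feature_id=feature_id, summaries=summaries, lfc=lfc, err=err,
        flagged=flagged, message=message,
    )


def _feature_seed(seed: int, index: int) -> int:
    """Independent, reproducible per-feature seed below 2**31."""
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def _uncertainty_and_prior(
    trend: GRFit | LGMRPosterior,
    nm: NormalizedMatrix,
    stats: PeptideStats,
) -> tuple[np.ndarray, SigmaPrior]:
    """Per-measurement uncertainty matrix and per-feature sigma prior from a trend."""
    if isinstance(trend, GRFit):
        u = predict_uncertainty_gr(trend, nm.values)
        prior = sigma_prior_gr(trend, stats)
        return u, prior
    if isinstance(trend, LGMRPosterior):
        # features absent from the fit (zero SD) fall back to the common trend
        theta = np.zeros(len(stats.feature_ids))
        pos = {fid: i for i, fid in enumerate(trend.feature_ids)}
        tmean = trend.theta_mean
        for i, fid in enumerate(stats.feature_ids):
            if fid in pos:
                theta[i] = tmean[pos[fid]]
        u = predict_uncertainty_lgmr(trend, trend.standardizer, theta[:, None], nm.values)
        mu = predict_uncertainty_lgmr(trend, trend.standardizer, theta, stats.ybar)
        alpha = trend.means["alpha"]
        return u, SigmaPrior(alpha=alpha, beta=alpha / mu)
    raise TypeError(f"unsupported trend model: {type(trend).__name__}")


def run_all(
    nm: NormalizedMatrix,
    trend: GRFit | LGMRPosterior,
    design: DesignMatrix | None = None,
    K: np.ndarray | ContrastSpec | None = None,
    prior: str = "eb",
    cfg: DecisionConfig | None = None,
) -> pd.DataFrame:
    """Run the decision model on every feature independently.

    Features are processed with per-feature seeds derived from the global
    seed, so results are identical for any worker count.  Per-feature
    sampler failures are collected in the ``message`` column, not fatal.
    """
    cfg = cfg or DecisionConfig()
    if design is None:
        design = design_from_conditions([nm.condition_of_sample[s] for s in nm.sample_ids])
    if K is None:
        raise ValueError("no contrasts")
    contrasts = K if isinstance(K, ContrastSpec) else validate_contrasts(K, design.n)

    stats = summarize_peptides(nm)
    u_matrix, sig_prior = _uncertainty_and_prior(trend, nm, stats)
    cond = design.condition_index
    C = design.n.size
    y = nm.values
    ybar_c = np.stack([y[:, cond == c].mean(axis=1) for c in range(C)], axis=1)

    def one(i: int) -> DecisionResult:
        inp = PeptideModelInput(
            y=y[i], u=u_matrix[i], alpha=sig_prior.alpha, beta=float(sig_prior.beta[i]),
            ybar_c=ybar_c[i],
        )
        fcfg = replace(cfg, seed=_feature_seed(cfg.seed, i))
        try:
            return sample_peptide(inp, design, contrasts, prior, fcfg, nm.feature_ids[i])
        except Exception as exc:
            M = contrasts.K.shape[1]
            return DecisionResult(
                feature_id=nm.feature_ids[i], summaries={},
                lfc=np.full(M, np.nan), err=np.full(M, np.nan),
                flagged=True, message=f"sampler failure: {exc}",
            )

    p = y.shape[0]
    if cfg.workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=cfg.workers)(delayed(one)(i) for i in range(p))
    else:
        results = [one(i) for i in range(p)]

    M = contrasts.K.shape[1]
    rows = []
    for r in results:
        row: dict = {"feature": r.feature_id}
        for m in range(M):
            row[f"lfc_{m}"] = r.lfc[m]
            row[f"err_{m}"] = r.err[m]
        if r.summaries:
            row["sigma_mean"] = r.summaries["sigma"]["mean"]
            row["sigma_rhat"] = r.summaries["sigma"]["rhat"]
            row["sigma_ess"] = r.summaries["sigma"]["ess"]
        else:
            row["sigma_mean"] = row["sigma_rhat"] = row["sigma_ess"] = np.nan
        row["flagged"] = r.flagged
        row["message"] = r.message
        rows.append(row)
    return pd.DataFrame(rows)
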