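"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

This is a multinomial NUTS implementation in the style of Stan's adaptive
HMC: momenta are Gaussian with a diagonal mass matrix estimated from warmup
draws in expanding memory windows, the step size is tuned by Nesterov dual
averaging toward a target acceptance statistic, and trajectories are grown
by tree doubling until a U-turn or divergence.  Models supply a single
callable returning the log joint density and its gradient on the
unconstrained scale (transforms and Jacobians are the model's concern).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ChainResult", "nuts_chain", "run_nuts", "rhat", "ess", "summarize_draws"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DIVERGENCE = 1000.0  # energy error declaring a divergent transition


def _logaddexp(a: float, b: float) -> float:
    if a == -math.inf:
        return b
    if b == -math.inf:
        return a
    m = a if a > b else b
    return m + math.log1p(math.exp(-abs(a - b)))


@dataclass
class _Tree:
    q_minus: np.ndarray
    r_minus: np.ndarray
    g_minus: np.ndarray
    q_plus: np.ndarray
    r_plus: np.ndarray
    g_plus: np.ndarray
    q_prop: np.ndarray
    lp_prop: float
    g_prop: np.ndarray
    logw: float
    stop: bool
    n_divergent: int
    sum_alpha: float
    n_alpha: int


@dataclass
class ChainResult:
    """Posterior draws and sampler diagnostics for one chain."""

    draws: np.ndarray  # (n_draws, dim), unconstrained scale
    logp: np.ndarray  # (n_draws,)
    accept_mean: float
    n_divergent: int
    step_size: float
    inv_mass: np.ndarray
    treedepth_mean: float = 0.0


def _kinetic(r: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(inv_mass * r, r))


def _leapfrog(
    logp_grad: LogpGrad,
    q: np.ndarray,
    r: np.ndarray,
    grad: np.ndarray,
    eps: float,
    inv_mass: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    r1 = r + 0.5 * eps * grad
    q1 = q + eps * inv_mass * r1
    lp1, g1 = logp_grad(q1)
    if not math.isfinite(lp1):
        # non-finite gradients surface as a non-finite Hamiltonian downstream
        return q1, r1, np.zeros_like(q1), -np.inf
    r1 = r1 + 0.5 * eps * g1
    return q1, r1, g1, lp1


def _uturn(dq: np.ndarray, r_minus: np.ndarray, r_plus: np.ndarray, inv_mass: np.ndarray) -> bool:
    return (
        float(np.dot(dq, inv_mass * r_minus)) < 0.0
        or float(np.dot(dq, inv_mass * r_plus)) < 0.0
    )


def _build_tree(
    logp_grad: LogpGrad,
    q: np.ndarray,
    r: np.ndarray,
    grad: np.ndarray,
    v: int,
    depth: int,
    eps: float,
    inv_mass: np.ndarray,
    h0: float,
    rng: np.random.Generator,
) -> _Tree:
    if depth == 0:
        q1, r1, g1, lp1 = _leapfrog(logp_grad, q, r, grad, v * eps, inv_mass)
        h = lp1 - _kinetic(r1, inv_mass) if np.isfinite(lp1) else -np.inf
        logw = h - h0
        divergent = not np.isfinite(logw) or logw < -_DIVERGENCE
        alpha = math.exp(min(0.0, logw)) if np.isfinite(logw) else 0.0
        return _Tree(
            q_minus=q1, r_minus=r1, g_minus=g1,
            q_plus=q1, r_plus=r1, g_plus=g1,
            q_prop=q1, lp_prop=lp1, g_prop=g1,
            logw=logw if np.isfinite(logw) else -np.inf,
            stop=divergent, n_divergent=int(divergent),
            sum_alpha=alpha, n_alpha=1,
        )

    inner = _build_tree(logp_grad, q, r, grad, v, depth - 1, eps, inv_mass, h0, rng)
    if inner.stop:
        return inner
    if v == 1:
        outer = _build_tree(
            logp_grad, inner.q_plus, inner.r_plus, inner.g_plus, v, depth - 1, eps, inv_mass, h0, rng
        )
        inner.q_plus, inner.r_plus, inner.g_plus = outer.q_plus, outer.r_plus, outer.g_plus
    else:
        outer = _build_tree(
            logp_grad, inner.q_minus, inner.r_minus, inner.g_minus, v, depth - 1, eps, inv_mass, h0, rng
        )
        inner.q_minus, inner.r_minus, inner.g_minus = outer.q_minus, outer.r_minus, outer.g_minus

    total = _logaddexp(inner.logw, outer.logw)
    # multinomial sampling within the subtree
    if math.log(rng.random() + 1e-300) < outer.logw - total:
        inner.q_prop, inner.lp_prop, inner.g_prop = outer.q_prop, outer.lp_prop, outer.g_prop
    inner.logw = total
    inner.n_divergent += outer.n_divergent
    inner.sum_alpha += outer.sum_alpha
    inner.n_alpha += outer.n_alpha
    inner.stop = outer.stop or _uturn(
        inner.q_plus - inner.q_minus, inner.r_minus, inner.r_plus, inv_mass
    )
    return inner


def _transition(
    logp_grad: LogpGrad,
    q: np.ndarray,
    logp: float,
    grad: np.ndarray,
    eps: float,
    inv_mass: np.ndarray,
    max_treedepth: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray, float, int, int]:
    r0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(r0, inv_mass)
    q_minus = q_plus = q
    r_minus = r_plus = r0
    g_minus = g_plus = grad
    q_prop, lp_prop, g_prop = q, logp, grad
    logw = 0.0
    sum_alpha, n_alpha, n_div = 0.0, 0, 0
    depth = 0
    while depth < max_treedepth:
        v = 1 if rng.random() < 0.5 else -1
        if v == 1:
            tree = _build_tree(logp_grad, q_plus, r_plus, g_plus, v, depth, eps, inv_mass, h0, rng)
            q_plus, r_plus, g_plus = tree.q_plus, tree.r_plus, tree.g_plus
        else:
            tree = _build_tree(logp_grad, q_minus, r_minus, g_minus, v, depth, eps, inv_mass, h0, rng)
            q_minus, r_minus, g_minus = tree.q_minus, tree.r_minus, tree.g_minus
        sum_alpha += tree.sum_alpha
        n_alpha += tree.n_alpha
        n_div += tree.n_divergent
        if tree.stop:
            break
        # biased progressive sampling favors the new subtree
        if math.log(rng.random() + 1e-300) < tree.logw - logw:
            q_prop, lp_prop, g_prop = tree.q_prop, tree.lp_prop, tree.g_prop
        logw = _logaddexp(logw, tree.logw)
        depth += 1
        if _uturn(q_plus - q_minus, r_minus, r_plus, inv_mass):
            break
    accept_stat = sum_alpha / max(n_alpha, 1)
    return q_prop, lp_prop, g_prop, accept_stat, n_div, depth


def _find_initial_step(
    logp_grad: LogpGrad,
    q: np.ndarray,
    logp: float,
    grad: np.ndarray,
    inv_mass: np.ndarray,
    rng: np.random.Generator,
    eps: float = 1.0,
) -> float:
    r = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(r, inv_mass)

    def energy_gain(e: float) -> float:
        q1, r1, _, lp1 = _leapfrog(logp_grad, q, r, grad, e, inv_mass)
        if not np.isfinite(lp1):
            return -np.inf
        return (lp1 - _kinetic(r1, inv_mass)) - h0

    direction = 1 if energy_gain(eps) > math.log(0.5) else -1
    for _ in range(60):
        gain = energy_gain(eps)
        if direction == 1 and gain <= math.log(0.5):
            break
        if direction == -1 and gain >= math.log(0.5):
            break
        eps *= 2.0**direction
        if not (1e-10 < eps < 1e7):
            break
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman-Gelman schedule)."""

    def __init__(self, eps0: float, target: float, gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept: float) -> float:
        self.count += 1
        eta = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - eta) * self.h_bar + eta * (self.target - accept)
        self.log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1.0 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


def _mass_windows(warmup: int) -> tuple[int, int, list[int]]:
    """Stan-style warmup split: step-size buffer, doubling variance windows, terminal buffer."""
    init_buf = max(1, int(round(0.15 * warmup)))
    term_buf = max(1, int(round(0.10 * warmup)))
    ends: list[int] = []
    t, w = init_buf, 25
    last = warmup - term_buf
    while t + w <= last:
        end = t + w
        if t + 3 * w > last:
            end = last
        ends.append(end)
        t = end
        w *= 2
    return init_buf, term_buf, ends


def nuts_chain(
    logp_grad: LogpGrad,
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> ChainResult:
    """Run one NUTS chain from ``q0`` and return post-warmup draws."""
    q = np.array(q0, dtype=float)
    dim = q.size
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_grad, q, logp, grad, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)
    init_buf, term_buf, window_ends = _mass_windows(n_warmup)

    # Welford accumulators for the variance windows
    w_n, w_mean, w_m2 = 0, np.zeros(dim), np.zeros(dim)
    n_div_total = 0

    for it in range(n_warmup):
        q, logp, grad, accept, n_div, _ = _transition(
            logp_grad, q, logp, grad, eps, inv_mass, max_treedepth, rng
        )
        n_div_total += n_div
        eps = da.update(accept)
        if init_buf <= it < (n_warmup - term_buf) and window_ends:
            w_n += 1
            delta = q - w_mean
            w_mean += delta / w_n
            w_m2 += delta * (q - w_mean)
            if it + 1 == window_ends[0]:
                window_ends.pop(0)
                if w_n >= 5:
                    var = w_m2 / max(w_n - 1, 1)
                    inv_mass = (w_n / (w_n + 5.0)) * var + 1e-3 * (5.0 / (w_n + 5.0))
                    inv_mass = np.clip(inv_mass, 1e-10, 1e10)
                w_n, w_mean, w_m2 = 0, np.zeros(dim), np.zeros(dim)
                eps = _find_initial_step(logp_grad, q, logp, grad, inv_mass, rng, eps)
                da = _DualAveraging(eps, target_accept)
    if n_warmup > 0:
        eps = da.adapted()

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    acc_sum, depth_sum, n_div_sampling = 0.0, 0, 0
    for it in range(n_draws):
        q, logp, grad, accept, n_div, depth = _transition(
            logp_grad, q, logp, grad, eps, inv_mass, max_treedepth, rng
        )
        draws[it] = q
        logps[it] = logp
        acc_sum += accept
        depth_sum += depth
        n_div_sampling += n_div
    return ChainResult(
        draws=draws,
        logp=logps,
        accept_mean=acc_sum / max(n_draws, 1),
        n_divergent=n_div_sampling,
        step_size=eps,
        inv_mass=inv_mass,
        treedepth_mean=depth_sum / max(n_draws, 1),
    )


def run_nuts(
    logp_grad: LogpGrad,
    init: np.ndarray | Callable[[np.random.Generator], np.ndarray],
    chains: int,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> tuple[np.ndarray, list[ChainResult]]:
    """Run several chains; returns draws with shape (chains, n_draws, dim)."""
    results = []
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(c,)))
        q0 = init(rng) if callable(init) else np.asarray(init, dtype=float)
        results.append(
            nuts_chain(logp_grad, q0, n_warmup, n_draws, rng, target_accept, max_treedepth)
        )
    draws = np.stack([r.draws for r in results])
    return draws, results


def rhat(chain_draws: np.ndarray) -> float:
    """Rank-normalized split R-hat for one scalar parameter, shape (chains, draws)."""
    import arviz as az

    out = az.rhat(np.asarray(chain_draws))
    return float(getattr(out, "x", out))


def ess(chain_draws: np.ndarray) -> float:
    """Bulk effective sample size for one scalar parameter, shape (chains, draws)."""
    import arviz as az

    out = az.ess(np.asarray(chain_draws))
    return float(getattr(out, "x", out))


def summarize_draws(chain_draws: np.ndarray) -> dict[str, float]:
    """Mean, median, central 95% interval, R-hat and ESS for one scalar parameter."""
    x = np.asarray(chain_draws)
    flat = x.reshape(-1)
    return {
        "mean": float(flat.mean()),
        "median": float(np.median(flat)),
        "q025": float(np.quantile(flat, 0.025)),
        "q975": float(np.quantile(flat, 0.975)),
        "rhat": rhat(x),
        "ess": ess(x),
    }
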