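"""Synthetic spike-in datasets with a known mean-variance structure.

The generator emulates a label-free spike-in benchmark: a constant
background of true negatives plus a subset of features whose condition
means differ by a known log2 fold change.  Per-feature SDs follow the
latent-mixture trend used by the regression models, so trend fitting,
uncertainty prediction and the decision model are all exercisable with
known ground truth and no external downloads.

Data are generated directly on the log2 scale (normalization assumed done);
``to_raw_scale`` exponentiates and injects per-sample scale factors to
exercise the preprocessing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lgmr import _mixture_mean
from .preprocess import NormalizedMatrix, QuantMatrix

__all__ = ["SimulationSpec", "SyntheticDataset", "simulate", "simulate_null", "to_raw_scale"]


@dataclass
class SimulationSpec:
    """Study conditions of one synthetic benchmark dataset.

    Trend parameters are on the latent-mixture scale: the expected SD at a
    standardized mean ``f`` is ``exp(g0 - gy*f) + kappa*exp(theta*(g0L - gyL*f))``.
    Defaults emulate a two-condition label-free experiment with four
    replicates, log2 abundances spread over (14, 22), SDs of roughly
    0.2-0.8 log2 units that shrink with abundance, a latent high-variance
    component concentrated at low abundance, and 10% spike-ins at one
    log2 unit fold change.
    """

    p: int = 1000
    conditions: int = 2
    replicates: int = 4
    gamma0: float = -0.7
    gamma_ybar: float = 0.35
    gamma0L: float = 4.0
    gamma_ybarL: float = 1.0
    kappa: float = 0.001
    alpha_shape: float = 3.0
    theta_mode: str = "uniform"  # "uniform", "zero" or "fixed"
    theta_fixed: float = 0.5
    spike_fraction: float = 0.1
    lfc: float = 1.0
    mean_range: tuple[float, float] = (14.0, 22.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike_fraction must lie in [0, 1]")
        if not np.isfinite(self.lfc):
            raise ValueError("lfc must be finite")
        if self.theta_mode not in ("uniform", "zero", "fixed"):
            raise ValueError("theta_mode must be 'uniform', 'zero' or 'fixed'")
        if self.alpha_shape <= 0 or self.kappa <= 0:
            raise ValueError("alpha_shape and kappa must be positive")
        if self.conditions < 2 or self.replicates < 2 or self.p < 1:
            raise ValueError("need >= 2 conditions, >= 2 replicates, >= 1 feature")


@dataclass
class SyntheticDataset:
    """Generated matrix, truth labels and the true per-feature parameters."""

    matrix: NormalizedMatrix
    truth: np.ndarray  # (p,) bool, spike-in membership
    params: dict = field(default_factory=dict)


def simulate(spec: SimulationSpec, contrast_conditions: tuple[int, int] = (0, 1)) -> SyntheticDataset:
    """Generate one dataset; deterministic under the spec's seed.

    Spike-in features split the fold change symmetrically (+-lfc/2) across
    the two conditions named by ``contrast_conditions``; other conditions
    stay at the feature's grand mean.
    """
    rng = np.random.default_rng(spec.seed)
    p, C, n = spec.p, spec.conditions, spec.replicates
    ybar = rng.uniform(*spec.mean_range, size=p)
    mu_y, sd_y = float(ybar.mean()), float(ybar.std(ddof=1))
    f = (ybar - mu_y) / sd_y
    if spec.theta_mode == "uniform":
        theta = rng.uniform(0.0, 1.0, size=p)
    elif spec.theta_mode == "zero":
        theta = np.zeros(p)
    else:
        theta = np.full(p, spec.theta_fixed)
    sd_expected = _mixture_mean(
        f, theta, spec.gamma0, spec.gamma0L, spec.gamma_ybar, spec.gamma_ybarL, spec.kappa
    )
    if not np.all(sd_expected > 0):
        raise ValueError("trend parameters produce non-positive expected SDs")
    sigma = rng.gamma(spec.alpha_shape, sd_expected / spec.alpha_shape)

    n_spike = int(round(spec.spike_fraction * p))
    truth = np.zeros(p, dtype=bool)
    truth[rng.choice(p, size=n_spike, replace=False)] = True

    cond_means = np.tile(ybar[:, None], (1, C))
    hi, lo = contrast_conditions
    cond_means[truth, hi] += spec.lfc / 2.0
    cond_means[truth, lo] -= spec.lfc / 2.0

    values = np.empty((p, C * n))
    sample_ids = []
    cond_of = {}
    for c in range(C):
        cols = slice(c * n, (c + 1) * n)
        values[:, cols] = cond_means[:, c, None] + sigma[:, None] * rng.standard_normal((p, n))
        for r in range(n):
            sid = f"cond{c + 1}_rep{r + 1}"
            sample_ids.append(sid)
            cond_of[sid] = f"cond{c + 1}"
    nm = NormalizedMatrix(
        feature_ids=[f"peptide_{i + 1}" for i in range(p)],
        values=values,
        sample_ids=sample_ids,
        condition_of_sample=cond_of,
    )
    return SyntheticDataset(
        matrix=nm,
        truth=truth,
        params={
            "ybar": ybar, "theta": theta, "sigma": sigma, "sd_expected": sd_expected,
            "mu_ybar": mu_y, "sd_ybar": sd_y, "spec": spec,
        },
    )


def simulate_null(spec: SimulationSpec) -> SyntheticDataset:
    """No-effect variant for false-positive calibration: lfc = 0, truth all false."""
    from dataclasses import replace

    ds = simulate(replace(spec, lfc=0.0, spike_fraction=0.0))
    ds.truth = np.zeros(spec.p, dtype=bool)
    return ds


def to_raw_scale(nm: NormalizedMatrix, scale_factors: np.ndarray, seed: int | None = None) -> QuantMatrix:
    """Exponentiate log2 data and multiply in per-sample scale factors."""
    s = np.asarray(scale_factors, dtype=float)
    if s.size != len(nm.sample_ids) or (s <= 0).any():
        raise ValueError("need one positive scale factor per sample")
    return QuantMatrix(
        feature_ids=list(nm.feature_ids),
        values=(2.0**nm.values) * s,
        sample_ids=list(nm.sample_ids),
        condition_of_sample=dict(nm.condition_of_sample),
    )
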