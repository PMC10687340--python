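"""Benchmark scoring against known spike-in truth.

Scores are error probabilities (or FDR-adjusted p-values); a feature is
called positive when its score does not exceed the significance threshold.
Decisions are swept over the closed interval [-0.1, 1] so ROC curves start
at the origin.  A pooled-variance t test with Benjamini-Hochberg adjustment
is provided as the frequentist comparator, and a replicate-subsampling
harness measures how TP/FP counts respond to sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .decision import ContrastSpec, DesignMatrix
from .preprocess import NormalizedMatrix

__all__ = [
    "ConfusionCounts",
    "MetricCurve",
    "confusion_at",
    "metrics",
    "roc",
    "t_test_baseline",
    "power_experiment",
]

DEFAULT_GRID = np.linspace(-0.1, 1.0, 1112)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricCurve:
    """TPR/FPR/precision/MCC along a significance-threshold sweep."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray  # NaN where no positive calls were made
    mcc: np.ndarray
    auroc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr,
             "precision": self.precision, "mcc": self.mcc}
        )


def confusion_at(scores: np.ndarray, truth: np.ndarray, alpha: float) -> ConfusionCounts:
    """Confusion counts calling positive iff score <= alpha."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    call = scores <= alpha
    return ConfusionCounts(
        tp=int(np.sum(call & truth)),
        fp=int(np.sum(call & ~truth)),
        tn=int(np.sum(~call & ~truth)),
        fn=int(np.sum(~call & truth)),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(TPR, FPR, precision, MCC).

    Precision is NaN when no positives were called; MCC is 0 by convention
    when any marginal count is zero.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    tpr = tp / (tp + fn) if tp + fn else np.nan
    fpr = fp / (fp + tn) if fp + tn else np.nan
    precision = tp / (tp + fp) if tp + fp else np.nan
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return tpr, fpr, precision, float(mcc)


def roc(scores: np.ndarray, truth: np.ndarray, grid: np.ndarray | None = None) -> MetricCurve:
    """Metric curve over the threshold grid; auROC by trapezoid over FPR."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.min() > -0.1 or grid.max() < 1.0:
        raise ValueError("grid must cover [-0.1, 1]")
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    # one pass: cumulative counts of sorted scores against the grid
    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    idx = np.searchsorted(sorted_scores, grid, side="right")
    cum_tp = np.concatenate([[0], np.cumsum(sorted_truth)])
    tp = cum_tp[idx].astype(float)
    called = idx.astype(float)
    fp = called - tp
    fn = n_pos - tp
    tn = n_neg - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(n_pos > 0, tp / max(n_pos, 1), np.nan)
        fpr = np.where(n_neg > 0, fp / max(n_neg, 1), np.nan)
        precision = np.where(called > 0, tp / np.maximum(called, 1), np.nan)
        denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(np.where(denom > 0, denom, 1.0)), 0.0)
    # integrate in threshold order; fpr is non-decreasing along the sweep
    auroc = float(np.trapezoid(tpr, fpr)) if n_pos and n_neg else np.nan
    return MetricCurve(thresholds=grid, tpr=tpr, fpr=fpr, precision=precision, mcc=mcc, auroc=auroc)


def t_test_baseline(
    nm: NormalizedMatrix,
    design: DesignMatrix,
    contrasts: ContrastSpec,
) -> pd.DataFrame:
    """Pooled-variance two-sample t test per pairwise contrast, BH-adjusted.

    Only pairwise columns of K (one +1 and one -1 entry) are supported;
    adjustment is applied within each comparison.
    """
    cond = design.condition_index
    out = {"feature": list(nm.feature_ids)}
    for m in range(contrasts.K.shape[1]):
        col = contrasts.K[:, m]
        pos = np.flatnonzero(col > 0)
        neg = np.flatnonzero(col < 0)
        if len(pos) != 1 or len(neg) != 1 or col[pos[0]] != 1.0 or col[neg[0]] != -1.0:
            raise ValueError(f"contrast column {m} is not pairwise; t test undefined")
        a = nm.values[:, cond == pos[0]]
        b = nm.values[:, cond == neg[0]]
        res = sps.ttest_ind(a, b, axis=1, equal_var=True)
        out[f"p_{m}"] = res.pvalue
        out[f"padj_{m}"] = multipletests(res.pvalue, method="fdr_bh")[1]
    return pd.DataFrame(out)


def power_experiment(
    nm: NormalizedMatrix,
    truth: np.ndarray,
    methods: dict,
    replicate_sizes: list[int],
    combos_per_size: int = 24,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """TP/FP at ``alpha`` as replicates are subsampled within condition.

    ``methods`` maps a method name to a callable ``f(sub_matrix) -> scores``
    (error probabilities or adjusted p-values, aligned with features).  For
    each requested replicate size, ``combos_per_size`` subsets are drawn
    without replacement within each condition; when the size uses every
    replicate the single deterministic subset is evaluated once.  Returns
    mean and SEM of TP and FP per method and size.
    """
    rng = np.random.default_rng(seed)
    cond_labels = [nm.condition_of_sample[s] for s in nm.sample_ids]
    by_cond: dict[str, list[int]] = {}
    for j, c in enumerate(cond_labels):
        by_cond.setdefault(c, []).append(j)
    truth = np.asarray(truth, dtype=bool)
    rows = []
    for size in replicate_sizes:
        if any(size > len(v) for v in by_cond.values()):
            raise ValueError(f"replicate size {size} exceeds available replicates")
        full = all(size == len(v) for v in by_cond.values())
        n_combo = 1 if full else combos_per_size
        counts: dict[str, list[tuple[int, int]]] = {name: [] for name in methods}
        for _ in range(n_combo):
            cols = sorted(
                j for v in by_cond.values() for j in rng.choice(v, size=size, replace=False)
            )
            sub = NormalizedMatrix(
                feature_ids=list(nm.feature_ids),
                values=nm.values[:, cols],
                sample_ids=[nm.sample_ids[j] for j in cols],
                condition_of_sample=dict(nm.condition_of_sample),
            )
            for name, fn in methods.items():
                scores = np.asarray(fn(sub), dtype=float)
                c = confusion_at(scores, truth, alpha)
                counts[name].append((c.tp, c.fp))
        for name, vals in counts.items():
            arr = np.asarray(vals, dtype=float)
            sem = arr.std(axis=0, ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.zeros(2)
            rows.append(
                {"method": name, "size": size, "n_combos": len(vals),
                 "tp_mean": arr[:, 0].mean(), "tp_sem": sem[0],
                 "fp_mean": arr[:, 1].mean(), "fp_sem": sem[1]}
            )
    return pd.DataFrame(rows)
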