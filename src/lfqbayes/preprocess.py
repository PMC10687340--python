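"""Reading, normalization and per-feature summaries of quantification matrices.

A quantification matrix holds one row per feature (peptide, protein, PTM
site) and one column per MS run.  Normalization follows the median-of-ratios
scheme: each sample is divided by the median, over rows with no missing
values, of the ratio of the measurement to the row's geometric mean across
samples.  Normalized data are log2-transformed; all downstream modeling
operates on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QuantMatrix",
    "NormalizedMatrix",
    "PeptideStats",
    "read_quant_matrix",
    "read_design",
    "compute_scale_factors",
    "normalize",
    "summarize_peptides",
]


@dataclass
class QuantMatrix:
    """Feature x sample abundance table with condition labels.

    Parameters
    ----------
    feature_ids
        Unique feature identifiers, one per row.
    values
        ``(p, m)`` array of raw-scale abundances; ``NaN`` marks missing.
    sample_ids
        Sample (column) names.
    condition_of_sample
        Mapping from sample id to condition label.
    """

    feature_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    condition_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p, m = self.values.shape
        if p < 1 or m < 2:
            raise ValueError("need at least 1 feature and 2 samples")
        if len(self.feature_ids) != p or len(self.sample_ids) != m:
            raise ValueError("id lengths inconsistent with value matrix")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")
        missing = [s for s in self.sample_ids if s not in self.condition_of_sample]
        if missing:
            raise ValueError(f"samples without condition: {missing}")

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition_of_sample[s], None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class NormalizedMatrix(QuantMatrix):
    """A :class:`QuantMatrix` on the log2 scale after scale-factor division."""

    log2: bool = field(default=True)


@dataclass
class PeptideStats:
    """Per-feature sample mean and sample SD (log2 units).

    ``ok`` flags features with positive SD; constant rows are excluded from
    trend fitting but can still be tested using the trend at their mean.
    """

    feature_ids: list[str]
    ybar: np.ndarray
    s: np.ndarray

    @property
    def ok(self) -> np.ndarray:
        return self.s > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_ids, "mean": self.ybar, "sd": self.s})


def read_quant_matrix(
    path: str,
    design: dict[str, str],
    id_column: str | None = None,
    sep: str | None = None,
) -> QuantMatrix:
    """Read a TSV/CSV with one identifier column and numeric sample columns."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if id_column is None:
        id_column = df.columns[0]
    df = df.set_index(id_column)
    samples = [c for c in df.columns if c in design]
    if not samples:
        raise ValueError("no sample columns matched the design")
    return QuantMatrix(
        feature_ids=[str(i) for i in df.index],
        values=df[samples].to_numpy(dtype=float),
        sample_ids=samples,
        condition_of_sample={s: design[s] for s in samples},
    )


def read_design(path: str, sep: str = "\t") -> dict[str, str]:
    """Read a two-column sample -> condition table."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("design file needs two columns: sample, condition")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def compute_scale_factors(q: QuantMatrix) -> np.ndarray:
    """Median-of-ratios scale factor per sample.

    For sample ``j``, ``s_j`` is the median over rows with no missing values
    of ``y_ij / gm_i`` where ``gm_i`` is the row's geometric mean across all
    ``m`` samples.  Only complete rows contribute.
    """
    y = q.values
    complete = ~np.isnan(y).any(axis=1)
    if not complete.any():
        raise ValueError("no complete rows")
    yc = y[complete]
    if (yc <= 0).any():
        raise ValueError("non-positive entries in complete rows")
    gm = np.exp(np.mean(np.log(yc), axis=1))
    return np.median(yc / gm[:, None], axis=0)


def normalize(
    q: QuantMatrix,
    s: np.ndarray | None = None,
    drop_missing: bool = True,
) -> NormalizedMatrix:
    """Divide each sample by its scale factor and log2-transform.

    Missing entries stay missing; rows containing missing values are dropped
    by default (``drop_missing=False`` passes them through for external
    imputation, but they must be resolved before trend or decision stages).
    """
    if s is None:
        s = compute_scale_factors(q)
    s = np.asarray(s, dtype=float)
    if (s <= 0).any():
        raise ValueError("scale factors must be positive")
    y = q.values
    bad = (y <= 0) & ~np.isnan(y)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive value at feature {q.feature_ids[i]!r}, sample {q.sample_ids[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        out = np.log2(y / s)
    keep = np.arange(out.shape[0])
    if drop_missing:
        keep = np.flatnonzero(~np.isnan(out).any(axis=1))
        out = out[keep]
    return NormalizedMatrix(
        feature_ids=[q.feature_ids[i] for i in keep],
        values=out,
        sample_ids=list(q.sample_ids),
        condition_of_sample=dict(q.condition_of_sample),
    )


def summarize_peptides(n: NormalizedMatrix) -> PeptideStats:
    """Per-feature mean and sample SD (n-1 denominator) pooled over all samples."""
    y = n.values
    if y.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(y).any():
        raise ValueError("missing values present; drop or impute first")
    ybar = y.mean(axis=1)
    s = y.std(axis=1, ddof=1)
    return PeptideStats(feature_ids=list(n.feature_ids), ybar=ybar, s=s)
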