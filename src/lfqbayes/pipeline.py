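"""End-to-end pipeline: preprocess -> trend fit -> per-feature decision.

``run_pipeline`` ties the stages together from file inputs to a results
table plus a JSON manifest (config echo, seed, versions, diagnostics) that
suffices to reproduce the run.  Results are deterministic for a fixed seed
and invariant to the worker count, because every feature's sampler seed is
derived from the global seed and the feature index.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decision import DecisionConfig, design_from_conditions, run_all, validate_contrasts
from .gamma_trend import fit_gr
from .lgmr import LGMRConfig, fit_lgmr
from .preprocess import normalize, read_design, read_quant_matrix, summarize_peptides

__all__ = ["RunConfig", "run_pipeline", "read_contrasts"]

log = logging.getLogger("lfqbayes")


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    input_path: str
    design_path: str
    contrasts_path: str
    output_dir: str
    trend: str = "gr"  # "gr" or "lgmr"
    prior: str = "eb"  # "eb" or "wi"
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    adapt_delta: float = 0.8
    scale_map: str = "xi"
    mu_h0: float = 0.0
    seed: int = 0
    workers: int = 1
    already_log2: bool = False  # input is normalized log2 data; skip scaling
    lgmr: LGMRConfig = field(default_factory=LGMRConfig)

    def validate_paths(self) -> None:
        for p in (self.input_path, self.design_path, self.contrasts_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def read_contrasts(path: str, condition_names: list[str]) -> np.ndarray:
    """Contrast TSV: first column condition labels, one column per contrast."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    missing = [c for c in condition_names if c not in df.index]
    if missing:
        raise ValueError(f"contrast file lacks rows for conditions: {missing}")
    return df.loc[condition_names].to_numpy(dtype=float)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    cfg.validate_paths()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "config": {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                   for k, v in asdict(cfg).items()},
        "versions": {"lfqbayes": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "seed": cfg.seed,
    }

    t0 = time.perf_counter()
    design_map = read_design(cfg.design_path)
    q = read_quant_matrix(cfg.input_path, design_map)
    if cfg.already_log2:
        from .preprocess import NormalizedMatrix

        nm = NormalizedMatrix(
            feature_ids=q.feature_ids, values=q.values,
            sample_ids=q.sample_ids, condition_of_sample=q.condition_of_sample,
        )
    else:
        nm = normalize(q)
    stats = summarize_peptides(nm)
    timings["preprocess"] = time.perf_counter() - t0
    log.info("preprocess: %d features, %d samples", len(nm.feature_ids), len(nm.sample_ids))

    design = design_from_conditions([nm.condition_of_sample[s] for s in nm.sample_ids])
    K_raw = read_contrasts(cfg.contrasts_path, design.condition_names)
    contrasts = validate_contrasts(K_raw, design.n)

    t0 = time.perf_counter()
    if cfg.trend == "gr":
        trend = fit_gr(stats)
        trend_report = {"model": "gr", "gamma0": trend.gamma0, "gamma_ybar": trend.gamma_ybar,
                        "shape": trend.shape, "nrmse": trend.nrmse}
    elif cfg.trend == "lgmr":
        from dataclasses import replace

        trend = fit_lgmr(stats, replace(cfg.lgmr, seed=cfg.seed))
        trend_report = {"model": "lgmr", **trend.report()}
    else:
        raise ValueError(f"unknown trend model {cfg.trend!r} (use 'gr' or 'lgmr')")
    timings["trend_fit"] = time.perf_counter() - t0
    log.info("trend fit (%s) done in %.1fs", cfg.trend, timings["trend_fit"])

    t0 = time.perf_counter()
    dec_cfg = DecisionConfig(
        chains=cfg.chains, warmup=cfg.warmup, draws=cfg.draws, adapt_delta=cfg.adapt_delta,
        seed=cfg.seed, scale_map=cfg.scale_map, mu_h0=cfg.mu_h0, workers=cfg.workers,
    )
    results = run_all(nm, trend, design, contrasts, prior=cfg.prior, cfg=dec_cfg)
    timings["decision"] = time.perf_counter() - t0
    n_flagged = int(results["flagged"].sum())
    if n_flagged:
        log.warning("%d features flagged (diagnostics or sampler failure)", n_flagged)

    results_path = out_dir / "results.tsv"
    results.to_csv(results_path, sep="\t", index=False)
    stats.to_frame().to_csv(out_dir / "peptide_stats.tsv", sep="\t", index=False)

    manifest.update(
        trend=trend_report,
        timings=timings,
        n_features=len(nm.feature_ids),
        n_flagged=n_flagged,
        outputs={"results": str(results_path), "peptide_stats": str(out_dir / "peptide_stats.tsv")},
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
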