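"""End-to-end orchestration: simulate -> screen -> normalize -> network ->
select -> validate, with per-stage TSV outputs and a reproducible manifest.

Stages communicate through plain TSV files in a run directory so any stage
can be re-run or resumed from the previous stage's outputs.  A single global
seed is fanned out to named per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as nio
from .boost import NetworkSparseBoostSelector
from .de import low_count_filter, nb_de_test, threshold_de
from .network import WeightedCoexpressionNetwork, export_links
from .simulate import SimulationConfig, simulate_cohort
from .survival import validate_genes
from .voom import voom_transform

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters plus paths, in one flat, overridable bundle."""

    outdir: str = "netsurv_run"
    counts_path: str | None = None      # None -> simulate a cohort
    clinical_path: str | None = None
    seed: int = 0
    # DE screen
    alpha: float = 0.05
    lfc: float = 2.0
    min_fraction: float = 0.2
    # network
    r2_target: float = 0.90
    max_power: int = 20
    min_module_size: int = 30
    cut_quantile: float = 0.90
    # selection
    max_iter: int = 500
    step_size: float = 0.1
    # validation
    logrank_alpha: float = 0.05
    # simulation overrides (used only when counts_path is None)
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.logrank_alpha < 1):
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.lfc < 0:
            raise ValueError("lfc must be non-negative")
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must lie in (0, 1]")
        if not (0 < self.cut_quantile < 1):
            raise ValueError("cut_quantile must lie in (0, 1)")
        if self.max_power < 1 or self.max_iter < 1 or self.min_module_size < 1:
            raise ValueError("max_power, max_iter, min_module_size must be >= 1")
        if not (0 < self.step_size <= 1):
            raise ValueError("step_size must lie in (0, 1]")


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream below 2**31 (stable across runs)."""
    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the run directory.

    Writes counts/clinical (simulated or copied), DE results, the filtered
    expression matrices, module memberships, the selection table, the
    log-rank validation table and a manifest with parameters, seed and
    per-stage gene counts.  Deterministic given the seed.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()},
        "stages": {},
    }
    t0 = _time.perf_counter()

    def _tick(stage):
        logger.info("stage %-9s done at %.1fs", stage, _time.perf_counter() - t0)

    # ---- inputs -----------------------------------------------------------
    stage = "input"
    try:
        if config.counts_path is None:
            sim = SimulationConfig(**{**config.simulation,
                                      "seed": _stage_seed(config.seed, "simulate")})
            counts, clinical, truth = simulate_cohort(sim)
            nio.write_counts(counts, out / "counts.tsv")
            nio.write_clinical(clinical, out / "clinical.tsv")
            nio.write_ground_truth(truth, out / "ground_truth.tsv")
        else:
            counts = nio.read_counts(config.counts_path)
            clinical = nio.read_clinical(config.clinical_path)
    except (ValueError, OSError, TypeError) as exc:
        raise PipelineError(stage, "bad_input", str(exc)) from exc
    manifest["stages"]["input"] = {"n_genes": int(counts.shape[0]),
                                   "n_samples": int(counts.shape[1])}
    _tick(stage)

    # ---- matching ---------------------------------------------------------
    stage = "match"
    try:
        normal, tumor, clin_tumor = nio.match_samples(counts, clinical)
        if tumor.shape[1] < 3 or normal.shape[1] < 2:
            raise ValueError("too few matched tumor or normal samples")
    except ValueError as exc:
        raise PipelineError(stage, "match_failed", str(exc)) from exc
    manifest["stages"]["match"] = {"n_normal": int(normal.shape[1]),
                                   "n_tumor": int(tumor.shape[1])}
    _tick(stage)

    # ---- DE screen then low-count filter ----------------------------------
    stage = "de"
    try:
        de_results = nb_de_test(normal, tumor)
        de_genes = threshold_de(de_results, config.alpha, config.lfc)
        de_results.to_csv(out / "de_results.tsv", sep="\t", index=False)
        if not de_genes:
            raise ValueError("no differentially expressed genes at the thresholds")
        screened = counts.loc[sorted(de_genes)]
        filtered = low_count_filter(screened, config.min_fraction)
    except ValueError as exc:
        raise PipelineError(stage, "de_failed", str(exc)) from exc
    n_up = int((de_results["gene_id"].isin(de_genes) & (de_results["log2fc"] > 0)).sum())
    manifest["stages"]["de"] = {
        "n_de": len(de_genes), "n_up": n_up, "n_down": len(de_genes) - n_up,
        "n_after_low_count_filter": int(filtered.shape[0]),
    }
    _tick(stage)

    # ---- normalization ----------------------------------------------------
    stage = "normalize"
    try:
        ordered = list(normal.columns) + list(tumor.columns)
        em = voom_transform(filtered[ordered],
                            group=np.concatenate([np.zeros(normal.shape[1], int),
                                                  np.ones(tumor.shape[1], int)]),
                            lib_size=counts[ordered].sum(axis=0).to_numpy())
        em.log_expr.to_csv(out / "log_expression.tsv", sep="\t", index_label="gene_id")
        em.weights.to_csv(out / "voom_weights.tsv", sep="\t", index_label="gene_id")
    except ValueError as exc:
        raise PipelineError(stage, "normalize_failed", str(exc)) from exc
    _tick(stage)

    # ---- network ----------------------------------------------------------
    stage = "network"
    try:
        tumor_expr = em.log_expr[list(tumor.columns)]
        net = WeightedCoexpressionNetwork(
            powers=tuple(range(1, config.max_power + 1)),
            r2_target=config.r2_target,
            min_module_size=config.min_module_size,
            cut_quantile=config.cut_quantile,
        ).fit(tumor_expr.T)
        modules = pd.DataFrame({"gene_id": tumor_expr.index,
                                "module": net.labels_})
        modules.to_csv(out / "modules.tsv", sep="\t", index=False)
        export_links(net.network_).to_csv(out / "links.tsv", sep="\t", index=False)
        curve = pd.DataFrame({"power": net.curve_.powers,
                              "fit_index": net.curve_.fit_index,
                              "mean_connectivity": net.curve_.mean_connectivity})
        curve.to_csv(out / "scale_free_curve.tsv", sep="\t", index=False)
    except ValueError as exc:
        raise PipelineError(stage, "network_failed", str(exc)) from exc
    module_sizes = modules["module"].value_counts().to_dict()
    manifest["stages"]["network"] = {
        "beta": int(net.beta_),
        "fit_at_beta": float(net.curve_.fit_index[list(net.curve_.powers).index(net.beta_)]),
        "n_modules": int(len([m for m in module_sizes if m != 0])),
        "noise_module_size": int(module_sizes.get(0, 0)),
    }
    _tick(stage)

    # ---- selection --------------------------------------------------------
    stage = "select"
    try:
        surv = clin_tumor.set_index("sample_id").loc[list(tumor.columns)]
        sel = NetworkSparseBoostSelector(
            max_iter=config.max_iter, step_size=config.step_size
        ).fit(
            tumor_expr.T,
            surv[["time", "event"]],
            module_labels=net.labels_,
        )
        rows = [
            {"gene_id": g,
             "module": next(m for m, mk in sel.per_module_.items()
                            if g in mk.member_genes),
             "estimate": est}
            for g, est in sorted(sel.module_estimates_.items())
        ]
        pd.DataFrame(rows, columns=["gene_id", "module", "estimate"]).to_csv(
            out / "selection.tsv", sep="\t", index=False
        )
    except ValueError as exc:
        raise PipelineError(stage, "select_failed", str(exc)) from exc
    manifest["stages"]["select"] = {
        "n_modules_selected": len(sel.selected_modules_),
        "n_genes_selected": len(sel.final_genes_),
    }
    _tick(stage)

    # ---- survival validation ----------------------------------------------
    stage = "survival"
    try:
        if sel.final_genes_:
            expr_sel = tumor_expr.loc[sorted(sel.final_genes_)]
            val = validate_genes(expr_sel, surv["time"], surv["event"])
        else:
            val = pd.DataFrame(columns=["gene_id", "chi2", "pvalue", "direction",
                                        "n_high", "n_low"])
        val.to_csv(out / "km_validation.tsv", sep="\t", index=False)
    except ValueError as exc:
        raise PipelineError(stage, "survival_failed", str(exc)) from exc
    manifest["stages"]["survival"] = {
        "n_significant": int((val["pvalue"] < config.logrank_alpha).sum())
        if len(val) else 0,
    }
    _tick(stage)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
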