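"""End-to-end orchestration: filter -> summaries -> trends -> gene panel ->
optional clustering / cluster panels / ratios -> optional conditional panel.

Artifacts are plain TSV/JSON under an output directory, with a run log
recording versions, seed and per-stage wall times. A stage failure stops
the run but preserves whatever was already written, plus a status file.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conditional import conditional_panel
from .genes import dataset_summary, filter_genes, run_gene_panel, summarize_genes
from .grouping import (
    ClusterAssignment,
    before_after_ratios,
    cluster_pipeline,
    cluster_specific_panel,
)
from .matrix import CountMatrix
from .trends import fit_variance_trend, fit_zero_trend

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str | Path = "spotcount_out"
    use_offset: bool = True
    alpha: float = 0.05
    bonferroni: bool = True
    boundary_mixture_null: bool = False
    do_clustering: bool = False
    min_cluster_size: int = 20
    n_hvg: int = 2000
    n_pcs: int = 15
    resolution: float = 0.5
    k_neighbors: int = 20
    seed: int = 0
    verbosity: int = 1
    extra: dict = field(default_factory=dict)


def _trend_record(tf) -> dict:
    return {
        "model": tf.model,
        "response": tf.response,
        "phi_hat": tf.phi_hat,
        "mse": tf.mse,
        "converged": tf.converged,
        "n_iter": tf.n_iter,
        "n_excluded": tf.n_excluded,
    }


def run_all(
    m: CountMatrix,
    config: RunConfig,
    compositions: pd.DataFrame | None = None,
    labels: np.ndarray | None = None,
) -> dict:
    """Run the full analysis; returns a bundle of in-memory results.

    ``labels`` (external cluster labels) bypasses clustering when given;
    otherwise clustering runs only when ``config.do_clustering`` is set.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    bundle: dict = {}
    status = {"ok": False, "failed_stage": None}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                log["stages"][name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    status["failed_stage"] = name
                    (out / "status.json").write_text(json.dumps(status, indent=1))
                    (out / "run_log.json").write_text(json.dumps(log, indent=1))
                return False

        return _T()

    with stage("filter"):
        m = filter_genes(m)
        bundle["matrix"] = m

    with stage("summaries"):
        summ = summarize_genes(m)
        summ.to_csv(out / "gene_summaries.tsv", sep="\t", index=False)
        ds = dataset_summary(summ)
        (out / "dataset_summary.json").write_text(json.dumps(ds, indent=1))
        bundle["summaries"], bundle["dataset_summary"] = summ, ds

    with stage("trends"):
        pos = summ[summ["mean"] > 0]
        trends = {
            "zero_poisson": fit_zero_trend(pos["mean"], pos["zero_prop"], "poisson"),
            "zero_nb": fit_zero_trend(pos["mean"], pos["zero_prop"], "nb"),
            "var_poisson": fit_variance_trend(pos["mean"], pos["variance"], "poisson"),
            "var_nb": fit_variance_trend(pos["mean"], pos["variance"], "nb"),
        }
        (out / "trends.json").write_text(
            json.dumps({k: _trend_record(v) for k, v in trends.items()}, indent=1)
        )
        pred = pd.DataFrame(
            {"gene": pos["gene"].to_numpy()}
            | {f"pred_{k}": v.predictions for k, v in trends.items()}
        )
        pred.to_csv(out / "trend_predictions.tsv", sep="\t", index=False)
        bundle["trends"] = trends

    with stage("gene_panel"):
        panel = run_gene_panel(
            m,
            alpha=config.alpha,
            bonferroni=config.bonferroni,
            boundary_mixture=config.boundary_mixture_null,
            use_offset=config.use_offset,
        )
        panel.to_csv(out / "gene_panel.tsv", sep="\t", index=False)
        bundle["panel"] = panel

    if labels is not None or config.do_clustering:
        with stage("clustering"):
            if labels is not None:
                ca = ClusterAssignment(labels=np.asarray(labels), params={"source": "external"})
            else:
                ca = cluster_pipeline(
                    m,
                    n_hvg=config.n_hvg,
                    n_pcs=config.n_pcs,
                    resolution=config.resolution,
                    k_neighbors=config.k_neighbors,
                    seed=config.seed,
                )
            pd.DataFrame(
                {"location": m.location_ids, "cluster": ca.labels}
            ).to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
            (out / "cluster_params.json").write_text(json.dumps(ca.params, indent=1))
            bundle["clusters"] = ca

        with stage("cluster_panel"):
            panels = cluster_specific_panel(
                m,
                ca,
                min_cluster_size=config.min_cluster_size,
                alpha=config.alpha,
                boundary_mixture=config.boundary_mixture_null,
            )
            for c, p in panels.items():
                p.to_csv(out / f"gene_panel_cluster{c}.tsv", sep="\t", index=False)
            ratios, medians = before_after_ratios(panel, panels)
            ratios.to_csv(out / "before_after_ratios.tsv", sep="\t", index=False)
            (out / "ratio_medians.json").write_text(json.dumps(medians, indent=1))
            bundle["cluster_panels"] = panels
            bundle["ratios"], bundle["ratio_medians"] = ratios, medians

    if compositions is not None:
        with stage("conditional"):
            comp = compositions.loc[[str(i) for i in m.location_ids]] if set(
                map(str, m.location_ids)
            ).issubset(set(map(str, compositions.index))) else compositions
            cpanel = conditional_panel(
                m,
                comp,
                alpha=config.alpha,
                boundary_mixture=config.boundary_mixture_null,
                use_offset=config.use_offset,
            )
            cpanel.to_csv(out / "gene_panel_conditional.tsv", sep="\t", index=False)
            bundle["conditional_panel"] = cpanel

    status["ok"] = True
    (out / "status.json").write_text(json.dumps(status, indent=1))
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    bundle["run_log"] = log
    return bundle
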