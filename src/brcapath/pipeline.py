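"""End-to-end pipeline: normalize -> screen -> networks -> cluster ->
enrich -> score -> trend -> classify.

Each stage consumes the previous stage's in-memory result, writes its
artifacts under ``out_dir`` and contributes to a single ``summary.json``.
The whole run is a pure function of (inputs, config, seed): rerunning with
identical inputs produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clustering, coexpression, enrichment, trend
from .classify import ClassifierSpec, fourclass_model, pairwise_models
from .exceptions import BrcaPathError, InputError
from .io import (
    SUBTYPES,
    read_expression,
    read_gene_sets,
    write_expression,
    zscore_rows,
)
from .pathway_score import score_matrix
from .screen import screen, venn_counts

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "normalize", "screen", "coexpr", "cluster",
    "enrich", "score", "trend", "classify",
)


@dataclass
class PipelineConfig:
    """All pipeline inputs, thresholds and toggles in one place.

    Every analysis default (0.05/0.01 screen thresholds, |r| > 0.5 edges,
    20/10 windows, LOESS span 0.75, C=1 RBF SVM) is a named field here,
    never hard-coded in a stage.
    """

    expression: str = ""
    labels: str = ""
    gmt: str = ""
    out_dir: str = "pipeline_out"
    alpha_anova: float = 0.05
    alpha_t: float = 0.01
    r_threshold: float = 0.5
    enrich_alpha: float = 0.05
    epsilon: float = 1e-6
    window_size: int = 20
    window_step: int = 10
    loess_span: float = 0.75
    svm_c: float = 1.0
    svm_gamma: float | None = None
    cluster_k: int = 4
    #: scale the alteration scores are computed on: "raw" uses the input
    #: expression values (stable reference ratios), "zscore" the
    #: row-normalized matrix (guards then handle near-zero references).
    score_scale: str = "raw"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if self.score_scale not in ("raw", "zscore"):
            raise InputError("score_scale must be 'raw' or 'zscore'")
        for name in ("alpha_anova", "alpha_t", "enrich_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InputError(f"{name} must lie in (0,1)")
        if self.window_step > self.window_size:
            raise InputError("window step must not exceed window size")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise InputError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the output manifest.

    Any stage failure aborts the run with the stage name attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict = {"seed": config.seed}
    stage = "load"

    def _emit(name: str, path: Path) -> None:
        manifest[name] = str(path.relative_to(out_dir))

    try:
        expr = read_expression(config.expression, config.labels)
        raw_expr = expr
        summary["n_genes"] = expr.n_genes
        summary["n_samples"] = expr.n_samples
        summary["n_per_subtype"] = {
            s: len(expr.subtype_samples(s)) for s in SUBTYPES
        }

        if "normalize" in config.stages:
            stage = "normalize"
            expr, flat_genes = zscore_rows(expr)
            summary["n_zero_variance_genes"] = len(flat_genes)
            p = out_dir / "expression.normalized.tsv"
            write_expression(expr, p)
            _emit("normalized_expression", p)

        collection = read_gene_sets(config.gmt, set(expr.genes))
        summary["n_gene_sets"] = len(collection)

        screen_result = None
        if "screen" in config.stages:
            stage = "screen"
            screen_result = screen(expr, config.alpha_anova, config.alpha_t)
            summary["screen"] = screen_result.to_dict()
            summary["venn_counts"] = venn_counts(screen_result.subtype_sets)
            p = out_dir / "screen.json"
            with open(p, "w", encoding="utf-8") as fh:
                json.dump(
                    {**screen_result.to_dict(), "venn_counts": summary["venn_counts"]},
                    fh, indent=1, sort_keys=True,
                )
            _emit("screen", p)

        core = screen_result.core_genes if screen_result else set()
        if "coexpr" in config.stages and screen_result:
            stage = "coexpr"
            summary["coexpression"] = {}
            for subtype in SUBTYPES:
                nodes = screen_result.subtype_sets[subtype]
                entry: dict = {"n_nodes": len(nodes)}
                if len(core) >= 2:
                    corr_core = coexpression.pearson_matrix(expr, core, subtype)
                    entry["core_pair_counts"] = {
                        str(t): c
                        for t, c in coexpression.pair_counts(corr_core).items()
                    }
                if len(nodes) >= 2:
                    corr = coexpression.pearson_matrix(expr, nodes, subtype)
                    net = coexpression.threshold_network(corr, config.r_threshold)
                    topo = coexpression.topology_summary(net)
                    entry["n_edges"] = len(net.edges)
                    if net.edges:
                        cc = coexpression.centrality_comparison(topo, core)
                        entry["core_mean_log10_degree"] = cc.core_mean_log10_degree
                        entry["all_mean_log10_degree"] = cc.all_mean_log10_degree
                        entry["all_sd_log10_degree"] = cc.all_sd_log10_degree
                    tag = subtype.replace("+", "p")
                    p = out_dir / f"network.{tag}.edges.tsv"
                    net.to_edge_frame().to_csv(p, sep="\t", index=False)
                    _emit(f"network_{tag}", p)
                    p = out_dir / f"network.{tag}.topology.tsv"
                    topo.to_frame().to_csv(p, sep="\t", index=False)
                    _emit(f"topology_{tag}", p)
                summary["coexpression"][subtype] = entry

        if "cluster" in config.stages and screen_result:
            stage = "cluster"
            union = set().union(*screen_result.subtype_sets.values())
            if len(core) >= 2 and len(union) >= 2:
                purity = clustering.compare_gene_sets(
                    expr, core, union, k=config.cluster_k
                )
                summary["cluster_purity"] = purity
                p = out_dir / "cluster.purity.json"
                with open(p, "w", encoding="utf-8") as fh:
                    json.dump(_round_floats(purity), fh, indent=1, sort_keys=True)
                _emit("cluster_purity", p)
            else:
                summary["cluster_purity"] = None

        enriched_pathways: list[str] = []
        if "enrich" in config.stages and screen_result:
            stage = "enrich"
            rows = enrichment.fisher_enrichment(
                core, collection, alpha=config.enrich_alpha
            )
            enriched_pathways = [r.pathway for r in rows if r.significant]
            summary["enrichment"] = {
                "n_significant": len(enriched_pathways),
                "significant_pathways": enriched_pathways,
            }
            p = out_dir / "enrichment.core.tsv"
            enrichment.enrichment_frame(rows).to_csv(
                p, sep="\t", index=False, float_format="%.6g"
            )
            _emit("enrichment_core", p)

        score_expr = raw_expr if config.score_scale == "raw" else expr
        scores = None
        if "score" in config.stages:
            stage = "score"
            pathways = enriched_pathways or collection.names()
            scores = score_matrix(
                score_expr, collection, pathways=pathways, epsilon=config.epsilon
            )
            summary["score"] = {
                "pathways": list(scores.pathways),
                "la_median_abs": float(
                    np.median(
                        np.abs(
                            np.median(
                                scores.subset_samples(
                                    expr.subtype_samples("LA")
                                ).scores,
                                axis=0,
                            )
                        )
                    )
                ),
            }
            p = out_dir / "scores.tsv"
            scores.to_frame().round(10).to_csv(p, sep="\t", index_label="sample")
            _emit("scores", p)

        if "trend" in config.stages and scores is not None:
            stage = "trend"
            series = trend.pathway_trends(
                scores, expr.labels,
                window_size=config.window_size,
                step=config.window_step,
                span=config.loess_span,
            )
            summary["trend"] = {
                "n_windows": len(series.windows),
                "has_partial_window": series.has_partial_window,
            }
            p = out_dir / "trend.tsv"
            series.to_frame().round(10).to_csv(p, sep="\t", index=False)
            _emit("trend", p)

        if "classify" in config.stages and scores is not None and screen_result:
            stage = "classify"
            spec = ClassifierSpec(
                C=config.svm_c, gamma=config.svm_gamma, seed=config.seed
            )
            report = fourclass_model(scores, expr.labels, spec)
            summary["classify"] = {"fourclass": report.to_dict()}
            pair_reports = pairwise_models(
                score_expr, screen_result, collection, spec,
                enrich_alpha=config.enrich_alpha, epsilon=config.epsilon,
            )
            summary["classify"]["pairwise"] = {
                f"{a}_vs_{b}": rep.to_dict() for (a, b), rep in pair_reports.items()
            }
            p = out_dir / "classification.json"
            with open(p, "w", encoding="utf-8") as fh:
                json.dump(_round_floats(summary["classify"]), fh, indent=1, sort_keys=True)
            _emit("classification", p)
    except BrcaPathError as exc:
        raise BrcaPathError(f"stage {stage!r} failed: {exc}") from exc

    summary_path = out_dir / "summary.json"
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(_round_floats(summary), fh, indent=1, sort_keys=True)
    manifest["summary"] = "summary.json"
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d artifacts in %s", len(manifest), out_dir)
    return manifest
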