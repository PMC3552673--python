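"""Orchestration of the full study analysis.

Stages, mirroring the study's narrative: present-call filter -> per-block
dose regression -> significance selections (both directions, analysis and
reporting cutoffs) -> probe collapsing -> gene-set enrichment; then, pooled
over both blocks: cross-timepoint overlap tests, grand-mean
centering + SD filter, Ward clustering of samples with heat-map export, and
the mutual-information network/module chain on the retained genes.

Every number in the RunReport is recomputed from the stage outputs; the
report is derived, never authoritative.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    ExpressionStudy,
    GeneSetCollection,
    collapse_probes,
    filter_present,
    read_annotation,
    read_expression,
    read_gmt,
)
from .dose_response import bh_fdr, fit_dose_regression, pvalue_histogram, select_genes
from .hypergeom_stats import enrich_gene_sets, overlap_significance
from .cluster_heatmap import (
    center_and_filter,
    cut_tree,
    hierarchical_cluster,
    pearson_dissimilarity,
    plot_heatmap,
)
from .mi_network import detect_modules, export_network, mi_adjacency, mi_distance

log = logging.getLogger("cdtox.pipeline")

__all__ = ["PipelineConfig", "run_block_analysis", "run_combined_analysis"]


@dataclass
class PipelineConfig:
    """Tunable analysis settings with the pipeline's defaults.

    ``sd_threshold`` applies to the scale selected by ``cluster_scale``:
    the study's MAS5-like default is raw signal with SD > 1; simulated
    log2-scale analyses typically use log2 with a threshold near the noise
    floor.
    """

    p_cutoff_analysis: float = 0.05
    p_cutoff_report: float = 0.01
    regression_scale: str = "raw"        # raw | log2
    collapse_rule: str = "min_p"         # min_p | max_abs_t
    gsea_level: str = "gene"             # gene | probe
    sd_threshold: float = 1.0
    cluster_scale: str = "raw"           # raw | log2
    sample_linkage: str = "ward"
    mi_bins: int = 3
    mi_scheme: str = "equal_frequency"
    mi_distance_mode: str = "one_minus_nmi"
    module_linkage: str = "average"
    min_module_size: int = 4
    n_candidate_cuts: int = 30
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _timed(report: dict, stage: str, started: float) -> None:
    report.setdefault("wall_time_s", {})[stage] = round(time.perf_counter() - started, 4)


def _scaled_matrix(study: ExpressionStudy, scale: str) -> pd.DataFrame:
    if scale == "log2":
        return np.log2(study.signal + 1.0)
    return study.signal


def run_block_analysis(
    study: ExpressionStudy,
    block: float,
    config: PipelineConfig,
    annotation: pd.DataFrame | None = None,
    gene_sets: GeneSetCollection | None = None,
    outdir=None,
) -> dict:
    """Analyze one exposure block; returns a report fragment.

    filter_present -> fit_dose_regression -> select_genes (both directions at
    both cutoffs) -> collapse_probes -> enrich_gene_sets.  All artifacts are
    written under ``outdir`` when given.
    """
    report: dict = {"block": block}
    t0 = time.perf_counter()
    present = filter_present(study)
    report["n_probes_input"] = len(study.probes)
    report["n_probes_present"] = len(present.probes)
    log.info("block %s: %d/%d probes present in >= 1 sample",
             block, report["n_probes_present"], report["n_probes_input"])
    _timed(report, "present_filter", t0)

    t0 = time.perf_counter()
    results = fit_dose_regression(present, block, scale=config.regression_scale,
                                  apply_present_filter=False)
    results = results.assign(q=bh_fdr(results))
    hist = pvalue_histogram(results, n_bins=20)
    report["n_significant_analysis"] = int((results["p"] < config.p_cutoff_analysis).sum())
    report["n_q_below_0_05"] = int((results["q"] < 0.05).sum())
    selections = {}
    for direction in ("positive", "negative"):
        for cutoff, tag in ((config.p_cutoff_analysis, "analysis"),
                            (config.p_cutoff_report, "report")):
            sel = select_genes(results, cutoff, direction)
            selections[(direction, tag)] = sel
            report[f"n_{direction}_{tag}"] = sel.n_selected
    log.info(
        "block %s: %d significant at P<%g; %d positive / %d negative at P<%g",
        block, report["n_significant_analysis"], config.p_cutoff_analysis,
        report["n_positive_report"], report["n_negative_report"], config.p_cutoff_report,
    )
    _timed(report, "regression", t0)

    gene_table = None
    if annotation is not None:
        gene_table = collapse_probes(results, annotation, rule=config.collapse_rule)
        report["n_genes_collapsed"] = len(gene_table)
    if gene_sets is not None:
        t0 = time.perf_counter()
        if config.gsea_level == "gene" and gene_table is not None:
            universe = list(gene_table.index)
            sig = gene_table.index[gene_table["p"] < config.p_cutoff_analysis]
        else:
            universe = list(results.index)
            sig = results.index[results["p"] < config.p_cutoff_analysis]
        enrichment = enrich_gene_sets(list(sig), universe, gene_sets)
        report["n_sets_tested"] = len(enrichment)
        report["n_sets_p_below_0_05"] = int((enrichment["p"] < 0.05).sum())
        _timed(report, "enrichment", t0)
    else:
        enrichment = None

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = f"block{block:g}"
        full = results
        if annotation is not None:
            full = results.join(annotation, how="left")
            cols = ["symbol", "gene_name", "slope", "intercept", "t", "p", "q",
                    "df", "direction", "perfect_fit"]
            full = full[[c for c in cols if c in full.columns]]
        full.rename(columns={"p": "Pr(>|t|)"}).rename_axis("probe").to_csv(
            outdir / f"regression_{tag}.tsv", sep="\t", float_format="%.6g")
        hist.to_csv(outdir / f"pvalue_hist_{tag}.tsv", sep="\t", index=False)
        if gene_table is not None:
            gene_table.to_csv(outdir / f"regression_{tag}_by_gene.tsv",
                              sep="\t", float_format="%.6g")
        if enrichment is not None:
            enrichment.to_csv(outdir / f"enrichment_{tag}.tsv",
                              sep="\t", float_format="%.6g")
    report["_results"] = results
    report["_selections"] = selections
    report["_gene_table"] = gene_table
    report["_enrichment"] = enrichment
    return report


def run_combined_analysis(
    study: ExpressionStudy,
    config: PipelineConfig,
    annotation: pd.DataFrame | None = None,
    gene_sets: GeneSetCollection | None = None,
    outdir=None,
    blocks: tuple[float, float] = (1.0, 13.0),
) -> dict:
    """Full two-block analysis: per-block stages, overlap tests, pooled
    clustering/heat map, and the MI network chain; returns the RunReport."""
    report: dict = {
        "version": __version__,
        "config": asdict(config),
        "blocks": {},
    }
    frags = {}
    for b in blocks:
        frag = run_block_analysis(study, b, config, annotation=annotation,
                                  gene_sets=gene_sets, outdir=outdir)
        frags[b] = frag
        report["blocks"][f"block{b:g}"] = {
            k: v for k, v in frag.items() if not k.startswith("_")
        }

    # cross-timepoint overlap on the reporting-cutoff lists, per direction
    t0 = time.perf_counter()
    present = filter_present(study)
    universe = list(
        set(frags[blocks[0]]["_results"].index) | set(frags[blocks[1]]["_results"].index)
    )
    report["overlap"] = {}
    for direction in ("positive", "negative"):
        a = frags[blocks[0]]["_selections"][(direction, "report")].ids
        b = frags[blocks[1]]["_selections"][(direction, "report")].ids
        res = overlap_significance(a, b, universe)
        report["overlap"][direction] = {
            "M": res.M, "K": res.K, "n": res.n, "r": res.r,
            "expected": res.expected, "p": res.p,
        }
        log.info("overlap (%s): r=%d of K=%d x n=%d in M=%d, P(X>r)=%.3g",
                 direction, res.r, res.K, res.n, res.M, res.p)
    _timed(report, "overlap", t0)

    # pooled clustering
    t0 = time.perf_counter()
    pooled = _scaled_matrix(present, config.cluster_scale)
    centered = center_and_filter(pooled, sd_threshold=config.sd_threshold)
    report["n_high_sd_genes"] = int(centered.mask.sum())
    log.info("%d genes with SD > %g retained for clustering/network",
             report["n_high_sd_genes"], config.sd_threshold)
    sample_dendro = gene_dendro = None
    if report["n_high_sd_genes"] >= 2:
        sample_dist = pearson_dissimilarity(centered.retained, axis="columns")
        sample_dendro = hierarchical_cluster(sample_dist, method=config.sample_linkage)
        k2 = cut_tree(sample_dendro, 2)
        report["sample_clusters_k2"] = {s: int(c) for s, c in k2.items()}
        try:
            gene_dist = pearson_dissimilarity(centered.retained, axis="rows")
            gene_dendro = hierarchical_cluster(gene_dist, method=config.sample_linkage)
        except ValueError:
            gene_dendro = None
    _timed(report, "clustering", t0)

    # MI network on the retained genes
    t0 = time.perf_counter()
    modules = []
    if report["n_high_sd_genes"] >= max(config.min_module_size + 1, config.mi_bins):
        mim = mi_adjacency(centered, B=config.mi_bins, scheme=config.mi_scheme)
        dist = mi_distance(mim, mode=config.mi_distance_mode)
        modules = detect_modules(
            mim, mode=config.mi_distance_mode, linkage=config.module_linkage,
            min_size=config.min_module_size, n_candidate_cuts=config.n_candidate_cuts,
            dist=dist,
        )
        report["modules"] = [
            {"size": m.size, "intra": m.intra, "extra": m.extra,
             "separation": m.separation, "members": list(m.members)}
            for m in modules[:10]
        ]
        if modules:
            log.info("top module: %d genes, separation %.3f bits",
                     modules[0].size, modules[0].separation)
    else:
        report["modules"] = []
        mim = dist = None
    _timed(report, "network", t0)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if sample_dendro is not None:
            (outdir / "samples.nwk").write_text(sample_dendro.to_newick() + "\n")
            sample_dendro.to_merge_table().to_csv(
                outdir / "sample_merges.tsv", sep="\t", index=False)
            plot_heatmap(centered, sample_dendro, gene_dendro,
                         path=outdir / "heatmap.png",
                         matrix_path=outdir / "heatmap_matrix.tsv")
        if mim is not None:
            export_network(mim, dist, modules,
                           edge_path=outdir / "network_edges.tsv",
                           module_path=outdir / "modules.tsv",
                           mi_path=outdir / "mi_matrix.tsv")
        with open(outdir / "overlap.json", "w", encoding="utf-8") as fh:
            json.dump(report["overlap"], fh, indent=2)
        clean = {k: v for k, v in report.items() if not k.startswith("_")}
        with open(outdir / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(clean, fh, indent=2, default=str)
        (outdir / "run_report.txt").write_text(_format_report(clean))
    report["_centered"] = centered
    report["_sample_dendro"] = sample_dendro
    report["_modules"] = modules
    report["_fragments"] = frags
    return report


def _format_report(report: dict) -> str:
    lines = [f"cdtox run report (version {report.get('version', '?')})", ""]
    for name, frag in report.get("blocks", {}).items():
        lines.append(
            f"{name}: {frag['n_probes_present']} present probes; "
            f"{frag['n_significant_analysis']} significant at the analysis cutoff; "
            f"{frag['n_positive_report']} positive / {frag['n_negative_report']} "
            f"negative at the reporting cutoff"
        )
    for direction, o in report.get("overlap", {}).items():
        lines.append(
            f"overlap ({direction}): r={o['r']} (expected {o['expected']:.2f}) "
            f"from lists of {o['K']} and {o['n']} in universe {o['M']}; "
            f"P(X>r) = {o['p']:.3g}"
        )
    lines.append(f"high-SD genes retained: {report.get('n_high_sd_genes')}")
    mods = report.get("modules", [])
    if mods:
        m = mods[0]
        lines.append(
            f"top network module: {m['size']} genes, separation "
            f"{m['separation']:.3f} bits ({', '.join(m['members'][:8])}"
            + (", ..." if m["size"] > 8 else "") + ")"
        )
    else:
        lines.append("no network module detected")
    return "\n".join(lines) + "\n"


def load_inputs(matrix, calls, design, annotation=None, gmt=None):
    """Convenience loader for the CLI: study plus optional annotation/sets."""
    study = read_expression(matrix, calls, design)
    ann = read_annotation(annotation) if annotation else None
    sets = read_gmt(gmt) if gmt else None
    return study, ann, sets
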