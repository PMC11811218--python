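"""End-to-end orchestration: quantified peaks + expression + annotation in,
machine-readable report out.

The stage order mirrors the analysis: signal filtering -> knockout/WT
fold changes -> induced RelB-site selection -> RelA profile clustering ->
nearest-TSS gene linking -> expression program selection/clustering ->
binding-expression integration. Every threshold, seed and pseudocount
used is echoed into the report for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import binding_clusters, chip_quant, expression_programs, integration, peak_gene_linking
from .core_io import (
    ExpressionMatrix,
    GeneAnnotationTable,
    PeakTable,
    ValidationError,
    read_annotation,
    read_expression,
    read_peak_table,
)

logger = logging.getLogger("kbcomp")

DEFAULT_FOLD_DIFFERENCE_PAIRS = (
    ("RelB_KO", "WT"),
    ("RelB_DB", "WT"),
    ("IFNAR_RelB_KO", "WT"),
    ("IFNAR_RelB_DB", "WT"),
    ("IFNAR_RelB_DB", "IFNAR_KO"),
)


@dataclass
class PipelineParams:
    """Analysis thresholds and pairings (defaults are the published ones)."""

    min_rpkm: float = 10.0
    rpkm_scope: str = "any_condition"
    chip_pseudocount: float = 1.0
    expr_pseudocount: float = 1.0
    induced_peak_log2fc: float = 1.0
    induced_gene_log2fc: float = 1.0
    hyper_fc: float = 1.5
    unchanged_band: tuple[float, float] = (-0.1, 0.1)
    k_peaks: int = 3
    k_genes: int = 2
    seed: int = 0
    restarts: int = 25
    chip_stimulus: str = "LPS"
    chip_time: float = 1.0
    expr_stimulus: str = "CpG"
    expr_time: float = 8.0
    genotype_ko: str = "RelB_KO"
    genotype_wt: str = "WT"
    induced_genotypes: tuple[str, ...] = ("WT", "RelB_KO")
    max_distance: float | None = None


@dataclass
class PipelineResult:
    """Tables from every stage plus the flat JSON-serializable report."""

    report: dict
    peak_fc: pd.Series
    peak_assignment: binding_clusters.ClusterAssignment | None
    peak_cluster_summary: pd.DataFrame | None
    gene_binding: pd.DataFrame
    programs: expression_programs.GeneProgramSelection
    gene_assignment: binding_clusters.ClusterAssignment | None
    fold_differences: pd.DataFrame | None
    integration_table: pd.DataFrame


def run_analysis(
    peaks: PeakTable,
    expr: ExpressionMatrix,
    annotation: GeneAnnotationTable,
    params: PipelineParams | None = None,
    program_genes=None,
) -> PipelineResult:
    """Run every stage on in-memory inputs.

    ``program_genes`` optionally supplies an external IFN-independent
    pro-inflammatory gene list (the integration subset); when absent the
    IFN-independent expression cluster ("A") stands in.
    """
    p = params or PipelineParams()
    report: dict = {"params": _params_dict(p)}

    # ChIP: filter, knockout/WT RelA fold change, distribution
    filtered = chip_quant.filter_min_signal(peaks, p.min_rpkm, p.rpkm_scope)
    report["n_peaks_total"] = int(len(peaks.peaks))
    report["n_peaks_filtered"] = int(len(filtered.peaks))
    rela_ko = filtered.condition_label(
        genotype=p.genotype_ko, stimulus=p.chip_stimulus,
        time_h=p.chip_time, assay="RelA_ChIP",
    )
    rela_wt = filtered.condition_label(
        genotype=p.genotype_wt, stimulus=p.chip_stimulus,
        time_h=p.chip_time, assay="RelA_ChIP",
    )
    peak_fc = chip_quant.log2_fold_change(
        filtered.signal[rela_ko], filtered.signal[rela_wt], p.chip_pseudocount
    )
    dist = chip_quant.summarize_distribution(peak_fc)
    report["peak_fc_distribution"] = dataclasses.asdict(dist)

    # induced RelB sites and RelA pattern clustering
    relb_stim = filtered.condition_label(
        genotype=p.genotype_wt, stimulus=p.chip_stimulus,
        time_h=p.chip_time, assay="RelB_ChIP",
    )
    relb_0h = filtered.condition_label(
        genotype=p.genotype_wt, stimulus="none", time_h=0.0, assay="RelB_ChIP"
    )
    induced = chip_quant.select_induced_peaks(
        filtered, relb_stim, relb_0h, p.induced_peak_log2fc, p.chip_pseudocount
    )
    report["n_induced_relb_peaks"] = int(len(induced.peaks))
    peak_assignment = cluster_summary = None
    if len(induced.peaks) >= p.k_peaks and p.k_peaks >= 1:
        rela_cols = [
            induced.condition_label(genotype=g, stimulus=s, time_h=t,
                                    assay="RelA_ChIP")
            for g, s, t in (
                (p.genotype_wt, "none", 0.0),
                (p.genotype_wt, p.chip_stimulus, p.chip_time),
                (p.genotype_ko, "none", 0.0),
                (p.genotype_ko, p.chip_stimulus, p.chip_time),
            )
        ]
        z = binding_clusters.zscore_rows(induced.signal[rela_cols])
        peak_assignment = binding_clusters.kmeans_cluster(
            z, k=p.k_peaks, seed=p.seed, restarts=p.restarts,
            rank_fc=peak_fc,
        )
        cluster_summary = binding_clusters.cluster_summaries(
            peak_assignment, peak_fc
        )
        report["peak_clusters"] = cluster_summary.to_dict(orient="records")

    # peak -> gene linking
    annotated = peak_gene_linking.annotate_nearest_gene(
        filtered, annotation, p.max_distance
    )
    gene_binding = peak_gene_linking.reduce_best_peak_per_gene(annotated, peak_fc)
    gene_dist = chip_quant.summarize_distribution(gene_binding["best_log2fc"])
    report["gene_fc_distribution"] = dataclasses.asdict(gene_dist)

    # expression programs
    programs = expression_programs.select_programs(
        expr,
        induced_genotypes=p.induced_genotypes,
        genotype_ko=p.genotype_ko,
        genotype_wt=p.genotype_wt,
        stimulus=p.expr_stimulus,
        induced_log2fc=p.induced_gene_log2fc,
        hyper_fc=p.hyper_fc,
        unchanged_band=p.unchanged_band,
        unchanged_reference_time=p.expr_time,
        pseudocount=p.expr_pseudocount,
    )
    report["n_induced_genes"] = len(programs.induced_genes)
    report["n_hyperexpressed_genes"] = len(programs.hyperexpressed_genes)
    report["n_unchanged_genes"] = len(programs.unchanged_genes)

    gene_assignment = fold_differences = None
    if len(programs.hyperexpressed_genes) >= p.k_genes and p.k_genes >= 1:
        gene_assignment = expression_programs.cluster_gene_programs(
            expr, programs.hyperexpressed_genes, k=p.k_genes, seed=p.seed,
            restarts=p.restarts, stimulus=p.expr_stimulus, late_time=p.expr_time,
        )
        report["gene_clusters"] = {
            str(k): int(v) for k, v in gene_assignment.sizes().items()
        }
        genotypes = {k.genotype for k in expr.conditions.values()}
        pairs = [
            pr for pr in DEFAULT_FOLD_DIFFERENCE_PAIRS
            if set(pr) <= genotypes
        ]
        times = sorted(
            {k.time_h for k in expr.conditions.values()
             if k.stimulus in (p.expr_stimulus, "none")}
        )
        if pairs:
            fold_differences = expression_programs.program_fold_differences(
                expr, gene_assignment, pairs, times, p.expr_stimulus,
                p.expr_pseudocount,
            )
            report["fold_differences"] = fold_differences.to_dict(orient="records")

    # integration
    if program_genes is None and gene_assignment is not None:
        program_genes = set(
            gene_assignment.labels.index[gene_assignment.labels == "A"]
        )
    program_genes = set() if program_genes is None else set(program_genes)
    table = integration.build_integration_table(
        gene_binding, expr, programs,
        expression_pair=(p.genotype_ko, p.genotype_wt),
        expression_stimulus=p.expr_stimulus,
        expression_time=p.expr_time,
        program_genes=program_genes,
        pseudocount=p.expr_pseudocount,
    )
    report["quadrant_counts"] = (
        table["quadrant"].value_counts().sort_index().to_dict()
    )
    if program_genes & set(table.index):
        conc = integration.quadrant_concordance(table, program_genes)
        report["concordance"] = {
            "n_total": conc.n_total,
            "n_upper_right": conc.n_upper_right,
            "fraction": conc.fraction,
        }
        linked = set(program_genes) & set(gene_binding.index)
        report["mean_tss_distance_bp"] = peak_gene_linking.mean_tss_distance(
            gene_binding, linked
        )
        unchanged = programs.unchanged_genes - program_genes
        if len(unchanged) >= 2:
            for test in ("welch_t", "mann_whitney"):
                cmp = integration.compare_binding_between_programs(
                    table, program_genes, unchanged, test=test
                )
                report[f"binding_comparison_{test}"] = dataclasses.asdict(cmp)

    return PipelineResult(
        report=report,
        peak_fc=peak_fc,
        peak_assignment=peak_assignment,
        peak_cluster_summary=cluster_summary,
        gene_binding=gene_binding,
        programs=programs,
        gene_assignment=gene_assignment,
        fold_differences=fold_differences,
        integration_table=table,
    )


def _params_dict(p: PipelineParams) -> dict:
    d = dataclasses.asdict(p)
    d["unchanged_band"] = list(d["unchanged_band"])
    d["induced_genotypes"] = list(d["induced_genotypes"])
    return d


# -- file-level driver -------------------------------------------------------


@dataclass
class PipelineConfig:
    """Input paths + analysis parameters, loadable from YAML."""

    peaks_bed: str
    chip_signal: str
    chip_samples: str
    rna_counts: str
    rna_samples: str
    annotation: str
    out_dir: str = "kbcomp_out"
    program_genes_path: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = raw.pop("params", {})
        if "unchanged_band" in params:
            params["unchanged_band"] = tuple(params["unchanged_band"])
        if "induced_genotypes" in params:
            params["induced_genotypes"] = tuple(params["induced_genotypes"])
        required = (
            "peaks_bed", "chip_signal", "chip_samples",
            "rna_counts", "rna_samples", "annotation",
        )
        missing = [k for k in required if k not in raw]
        if missing:
            raise ValidationError(f"pipeline config missing field(s): {missing}")
        return cls(params=PipelineParams(**params), **raw)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read inputs, run every stage, and write per-stage TSVs plus a single
    JSON report into ``config.out_dir``."""
    for name in ("peaks_bed", "chip_signal", "chip_samples", "rna_counts",
                 "rna_samples", "annotation"):
        path = getattr(config, name)
        if not os.path.exists(path):
            raise ValidationError(f"config field {name}: no such file {path!r}")
    peaks = read_peak_table(config.peaks_bed, config.chip_signal, config.chip_samples)
    expr = read_expression(config.rna_counts, config.rna_samples)
    annotation = read_annotation(config.annotation)
    program_genes = None
    if config.program_genes_path:
        with open(config.program_genes_path) as fh:
            program_genes = {line.strip() for line in fh if line.strip()}
    result = run_analysis(peaks, expr, annotation, config.params, program_genes)

    os.makedirs(config.out_dir, exist_ok=True)
    j = lambda name: os.path.join(config.out_dir, name)  # noqa: E731
    result.gene_binding.to_csv(j("gene_binding.tsv"), sep="\t",
                               index_label="gene_id", float_format="%.6f")
    result.integration_table.to_csv(j("integration.tsv"), sep="\t",
                                    index_label="gene_id", float_format="%.6f")
    if result.peak_assignment is not None:
        result.peak_assignment.labels.rename("cluster").to_csv(
            j("peak_clusters.tsv"), sep="\t", index_label="peak_id"
        )
        result.peak_cluster_summary.to_csv(
            j("peak_cluster_summary.tsv"), sep="\t", index=False,
            float_format="%.6f",
        )
    if result.gene_assignment is not None:
        result.gene_assignment.labels.rename("program").to_csv(
            j("gene_programs.tsv"), sep="\t", index_label="gene_id"
        )
    if result.fold_differences is not None:
        result.fold_differences.to_csv(
            j("fold_differences.tsv"), sep="\t", index=False, float_format="%.6f"
        )
    with open(j("report.json"), "w") as fh:
        json.dump(result.report, fh, indent=1, sort_keys=True)
    logger.info("pipeline report written to %s", j("report.json"))
    return result
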