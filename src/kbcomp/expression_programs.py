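"""CPM normalization, stimulus-induced gene selection and expression
program clustering.

Selection rules (all strict inequalities, computed on pseudocounted CPM):

* induced: log2((cpm_t + 1) / (cpm_0h + 1)) > 1 at any stimulated time in
  any qualifying genotype, after removing transcripts with empty gene
  names;
* hyper-expressed: (cpm_ko + 1) / (cpm_wt + 1) > 1.5 at >= 1 time point
  (0 h included), within the induced set;
* unchanged: -0.1 < log2FC < 0.1 at the reference time (8 h), open
  interval, restricted to detectable genes (CPM >= 1 somewhere) by
  default.

Programs are the k = 2 k-means clusters of the z-scored CPM profile over
the genotype x time grid; the cluster that collapses in IFNAR-/-
backgrounds at the late time point is the IFN-dependent program ("B"),
the other the IFN-independent program ("A").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding_clusters import ClusterAssignment, kmeans_cluster, zscore_rows
from .core_io import ExpressionMatrix, ValidationError

IFNAR_BACKGROUNDS = ("IFNAR_KO", "IFNAR_RelB_KO", "IFNAR_RelB_DB")


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """CPM = 1e6 * count / column sum; every output column sums to 1e6."""
    colsum = counts.sum(axis=0)
    if (colsum <= 0).any():
        bad = list(colsum.index[colsum <= 0])
        raise ValidationError(f"zero library size for sample(s) {bad[:5]}")
    return counts * 1e6 / colsum


def expression_log2fc(cpm_a, cpm_b, pseudocount: float = 1.0):
    """log2((a + p) / (b + p)) with the 1-CPM pseudocount default."""
    from .chip_quant import log2_fold_change

    return log2_fold_change(cpm_a, cpm_b, pseudocount)


def _stimulated_labels(expr: ExpressionMatrix, genotype: str, stimulus: str):
    labs = [
        lab
        for lab, key in expr.conditions.items()
        if key.genotype == genotype and key.stimulus == stimulus and key.time_h > 0
    ]
    return sorted(labs, key=lambda lab: expr.conditions[lab].time_h)


def _reference_label(expr: ExpressionMatrix, genotype: str) -> str:
    return expr.condition_label(genotype=genotype, stimulus="none", time_h=0)


def select_induced_genes(
    expr: ExpressionMatrix,
    genotypes,
    stimulus: str,
    min_log2fc: float = 1.0,
    pseudocount: float = 1.0,
) -> set[str]:
    """Genes induced above ``min_log2fc`` (strict) versus the 0 h control in
    ANY listed genotype at ANY stimulated time; empty-name transcripts are
    removed first."""
    named = expr.gene_names.index[expr.gene_names != ""]
    induced = pd.Series(False, index=named)
    for genotype in genotypes:
        ref = _reference_label(expr, genotype)
        stim = _stimulated_labels(expr, genotype, stimulus)
        if not stim:
            raise ValidationError(
                f"no stimulated {stimulus} samples for genotype {genotype}"
            )
        base = expr.cpm.loc[named, ref]
        for lab in stim:
            fc = expression_log2fc(expr.cpm.loc[named, lab], base, pseudocount)
            induced |= fc > min_log2fc
    return set(induced.index[induced])


def select_hyperexpressed(
    expr: ExpressionMatrix,
    genotype_ko: str,
    genotype_wt: str,
    stimulus: str,
    min_fc: float = 1.5,
    within: set[str] | None = None,
    pseudocount: float = 1.0,
) -> set[str]:
    """Genes whose pseudocounted CPM ratio ko/wt strictly exceeds ``min_fc``
    at >= 1 time point (0 h included), restricted to ``within`` if given."""
    genes = expr.cpm.index if within is None else pd.Index(sorted(within))
    ko_labs = [_reference_label(expr, genotype_ko)] + _stimulated_labels(
        expr, genotype_ko, stimulus
    )
    wt_labs = [_reference_label(expr, genotype_wt)] + _stimulated_labels(
        expr, genotype_wt, stimulus
    )
    if len(ko_labs) != len(wt_labs):
        raise ValidationError("genotypes do not share the time grid")
    hyper = pd.Series(False, index=genes)
    for ko_lab, wt_lab in zip(ko_labs, wt_labs):
        ratio = (expr.cpm.loc[genes, ko_lab] + pseudocount) / (
            expr.cpm.loc[genes, wt_lab] + pseudocount
        )
        hyper |= ratio > min_fc
    return set(hyper.index[hyper])


def select_unchanged(
    expr: ExpressionMatrix,
    genotype_ko: str,
    genotype_wt: str,
    stimulus: str,
    band: tuple[float, float] = (-0.1, 0.1),
    reference_time: float = 8.0,
    require_detectable: bool = True,
    pseudocount: float = 1.0,
) -> set[str]:
    """Genes with ko/wt log2FC inside the open interval ``band`` at the
    reference stimulated time point."""
    lo, hi = band
    ko = expr.condition_label(genotype=genotype_ko, stimulus=stimulus,
                              time_h=reference_time)
    wt = expr.condition_label(genotype=genotype_wt, stimulus=stimulus,
                              time_h=reference_time)
    fc = expression_log2fc(expr.cpm[ko], expr.cpm[wt], pseudocount)
    keep = (fc > lo) & (fc < hi)
    if require_detectable:
        keep &= (expr.cpm >= 1.0).any(axis=1)
    return set(fc.index[keep])


@dataclass
class GeneProgramSelection:
    """Induced / hyper-expressed / unchanged gene sets with the thresholds
    that produced them. Unchanged is disjoint from hyper-expressed by
    construction."""

    induced_genes: set[str]
    hyperexpressed_genes: set[str]
    unchanged_genes: set[str]
    selection_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.hyperexpressed_genes <= self.induced_genes:
            raise ValidationError("hyper-expressed genes must be induced")
        self.unchanged_genes = set(self.unchanged_genes) - set(
            self.hyperexpressed_genes
        )


def select_programs(
    expr: ExpressionMatrix,
    induced_genotypes=("WT", "RelB_KO"),
    genotype_ko: str = "RelB_KO",
    genotype_wt: str = "WT",
    stimulus: str = "CpG",
    induced_log2fc: float = 1.0,
    hyper_fc: float = 1.5,
    unchanged_band: tuple[float, float] = (-0.1, 0.1),
    unchanged_reference_time: float = 8.0,
    pseudocount: float = 1.0,
) -> GeneProgramSelection:
    """Run the three selections with one parameter set."""
    induced = select_induced_genes(
        expr, induced_genotypes, stimulus, induced_log2fc, pseudocount
    )
    hyper = select_hyperexpressed(
        expr, genotype_ko, genotype_wt, stimulus, hyper_fc, induced, pseudocount
    )
    unchanged = select_unchanged(
        expr, genotype_ko, genotype_wt, stimulus, unchanged_band,
        unchanged_reference_time, pseudocount=pseudocount,
    )
    params = {
        "induced_genotypes": list(induced_genotypes),
        "genotype_ko": genotype_ko,
        "genotype_wt": genotype_wt,
        "stimulus": stimulus,
        "induced_log2fc": induced_log2fc,
        "hyper_fc": hyper_fc,
        "unchanged_band": list(unchanged_band),
        "unchanged_reference_time": unchanged_reference_time,
        "pseudocount": pseudocount,
    }
    return GeneProgramSelection(induced, hyper, unchanged, params)


def cluster_gene_programs(
    expr: ExpressionMatrix,
    genes,
    k: int = 2,
    seed: int = 0,
    restarts: int = 25,
    stimulus: str = "CpG",
    late_time: float = 8.0,
    ifn_genotypes=IFNAR_BACKGROUNDS,
) -> ClusterAssignment:
    """k-means on z-scored CPM profiles of ``genes`` over every genotype x
    time column.

    For k = 2 the clusters are named by an IFN-dependence score: the
    cluster with the lower mean z-score in IFNAR-/--background columns at
    the late time point is "B" (IFN-dependent), the other "A".
    """
    genes = pd.Index(sorted(genes))
    cols = [
        lab
        for lab, key in sorted(expr.conditions.items())
        if key.stimulus in (stimulus, "none")
    ]
    z = zscore_rows(expr.cpm.loc[genes, cols])
    assignment = kmeans_cluster(z, k=k, seed=seed, restarts=restarts)
    ifn_cols = [
        lab
        for lab in cols
        if expr.conditions[lab].genotype in set(ifn_genotypes)
        and expr.conditions[lab].time_h == late_time
    ]
    if ifn_cols:
        score = z[ifn_cols].mean(axis=1).groupby(assignment.labels).mean()
        order = score.sort_values(ascending=False)  # lowest score last -> "B"
        import string as _string

        assignment = assignment.relabel(
            dict(zip(order.index, _string.ascii_uppercase))
        )
    return assignment


def program_fold_differences(
    expr: ExpressionMatrix,
    assignment: ClusterAssignment,
    genotype_pairs,
    times,
    stimulus: str = "CpG",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-cluster, per-time arithmetic mean of the per-gene CPM fold
    difference (x + 1) / (y + 1) for each genotype pair.

    Columns: cluster, time_h, pair, mean_fold_difference.
    """
    rows = []
    for cluster, members in assignment.labels.groupby(assignment.labels).groups.items():
        if len(members) == 0:
            raise ValidationError(f"empty cluster {cluster}")
        for gx, gy in genotype_pairs:
            for t in times:
                stim = "none" if t == 0 else stimulus
                cx = expr.condition_label(genotype=gx, stimulus=stim, time_h=t)
                cy = expr.condition_label(genotype=gy, stimulus=stim, time_h=t)
                fd = (expr.cpm.loc[members, cx] + pseudocount) / (
                    expr.cpm.loc[members, cy] + pseudocount
                )
                rows.append(
                    {
                        "cluster": cluster,
                        "time_h": float(t),
                        "pair": f"{gx}/{gy}",
                        "mean_fold_difference": float(fd.mean()),
                    }
                )
    return pd.DataFrame(rows)
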