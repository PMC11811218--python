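"""Joining per-gene binding change with expression change.

The published condition pairing is preserved as parameters: the binding axis is the
RelA knockout/WT log2FC at 1 h LPS (from the best peak per gene), the
expression axis the knockout/WT log2FC at 8 h CpG. Quadrants use a strict
> 0 rule for "elevated" on both axes; an exact zero falls to the
left/below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, ValidationError
from .expression_programs import GeneProgramSelection, expression_log2fc

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")  # (+,+), (-,+), (-,-), (+,-)


def _quadrant(binding: float, expression: float) -> str:
    if binding > 0:
        return "Q1" if expression > 0 else "Q4"
    return "Q2" if expression > 0 else "Q3"


@dataclass(frozen=True)
class ConcordanceResult:
    n_total: int
    n_upper_right: int

    @property
    def fraction(self) -> float:
        return self.n_upper_right / self.n_total


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    n_a: int
    n_b: int


def build_integration_table(
    summaries: pd.DataFrame,
    expr: ExpressionMatrix,
    programs: GeneProgramSelection,
    expression_pair=("RelB_KO", "WT"),
    expression_stimulus: str = "CpG",
    expression_time: float = 8.0,
    program_genes=None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One row per gene present in both the binding summaries and the
    expression matrix: binding_log2fc, expression_log2fc, program, quadrant.

    ``program_genes`` designates the IFN-independent hyper-expressed set
    (e.g. an externally supplied pro-inflammatory gene list); genes in the
    unchanged selection are labelled "unchanged", everything else "other".
    """
    ko, wt = expression_pair
    ko_lab = expr.condition_label(genotype=ko, stimulus=expression_stimulus,
                                  time_h=expression_time)
    wt_lab = expr.condition_label(genotype=wt, stimulus=expression_stimulus,
                                  time_h=expression_time)
    genes = summaries.index.intersection(expr.cpm.index)
    if len(genes) == 0:
        raise ValidationError("binding summaries and expression share no genes")
    n_dropped = len(summaries) - len(genes)
    if n_dropped:
        import logging

        logging.getLogger("kbcomp").info(
            "integration: %d gene(s) without expression dropped", n_dropped
        )
    expr_fc = expression_log2fc(
        expr.cpm.loc[genes, ko_lab], expr.cpm.loc[genes, wt_lab], pseudocount
    )
    program_genes = set() if program_genes is None else set(program_genes)
    table = pd.DataFrame(
        {
            "binding_log2fc": summaries.loc[genes, "best_log2fc"],
            "expression_log2fc": expr_fc,
        }
    )
    table["program"] = "other"
    table.loc[table.index.isin(programs.unchanged_genes), "program"] = "unchanged"
    table.loc[table.index.isin(program_genes), "program"] = "ifn_independent_hyper"
    table["quadrant"] = [
        _quadrant(b, e)
        for b, e in zip(table["binding_log2fc"], table["expression_log2fc"])
    ]
    return table.sort_index()


def quadrant_concordance(table: pd.DataFrame, gene_subset) -> ConcordanceResult:
    """Fraction of ``gene_subset`` genes with both binding and expression
    log2FC strictly positive (upper-right quadrant)."""
    genes = table.index.intersection(pd.Index(sorted(set(gene_subset))))
    if len(genes) == 0:
        raise ValidationError("gene subset does not intersect the table")
    sub = table.loc[genes]
    upper_right = (sub["binding_log2fc"] > 0) & (sub["expression_log2fc"] > 0)
    return ConcordanceResult(n_total=int(len(sub)),
                             n_upper_right=int(upper_right.sum()))


def compare_binding_between_programs(
    table: pd.DataFrame, set_a, set_b, test: str = "welch_t"
) -> GroupComparison:
    """Two-sided comparison of binding log2FC between two disjoint gene sets
    (Welch's t by default, Mann-Whitney U as the rank alternative)."""
    set_a, set_b = set(set_a), set(set_b)
    if set_a & set_b:
        raise ValidationError("gene sets overlap")
    a = table.loc[table.index.intersection(pd.Index(sorted(set_a))), "binding_log2fc"]
    b = table.loc[table.index.intersection(pd.Index(sorted(set_b))), "binding_log2fc"]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("both gene sets need >= 2 genes with binding data")
    av, bv = a.to_numpy(float), b.to_numpy(float)
    if test == "welch_t":
        if np.ptp(av) == 0 and np.ptp(bv) == 0 and av[0] == bv[0]:
            stat, p = 0.0, 1.0  # degenerate identical constants
        else:
            stat, p = stats.ttest_ind(av, bv, equal_var=False)
    elif test == "mann_whitney":
        stat, p = stats.mannwhitneyu(av, bv, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(test=test, statistic=float(stat), pvalue=float(p),
                           n_a=len(a), n_b=len(b))
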