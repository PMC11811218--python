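"""Nearest-TSS peak annotation and reduction to one peak per gene.

Each peak is assigned to the gene whose TSS is closest to the peak
center (floor((start + end) / 2)); the reported distance is signed and
strand-aware: negative means the peak center lies upstream of the TSS
with respect to the gene's orientation. Equidistant TSSs are broken
deterministically by lexicographic gene_id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import GeneAnnotationTable, PeakTable, ValidationError


def annotate_nearest_gene(
    peaks: PeakTable, genes: GeneAnnotationTable, max_distance: float | None = None
) -> pd.DataFrame:
    """Peak -> (gene_id, tss_distance) table indexed by peak_id.

    Peaks on chromosomes without genes (or beyond ``max_distance``, when
    set) are omitted and counted in the log.
    """
    centers = peaks.peak_centers
    chroms = peaks.peaks["chrom"]
    gtab = genes.genes
    rows = []
    for chrom, idx in centers.groupby(chroms).groups.items():
        g = gtab[gtab["chrom"] == chrom]
        if g.empty:
            continue
        # sorted by (tss, gene_id): within a tss-value run the first entry is
        # the lexicographically smallest gene, matching the tie-break rule
        g = g.assign(gene_id=g.index.to_numpy()).reset_index(drop=True)
        g = g.sort_values(["tss", "gene_id"], kind="mergesort")
        tss = g["tss"].to_numpy()
        gid = g["gene_id"].to_numpy()
        strand = g["strand"].to_numpy()
        # first index of each distinct tss value (duplicates resolved to the
        # smallest gene_id at that position)
        uniq_tss, first_idx = np.unique(tss, return_index=True)
        c = centers.loc[idx].to_numpy()
        pos = np.searchsorted(uniq_tss, c)
        for peak_id, center, p in zip(idx, c, pos):
            cand = []
            if p > 0:
                cand.append(first_idx[p - 1])
            if p < len(uniq_tss):
                cand.append(first_idx[p])
            best = min(cand, key=lambda i: (abs(center - tss[i]), gid[i]))
            d = int(center - tss[best])
            signed = d if strand[best] == "+" else -d
            if max_distance is not None and abs(d) > max_distance:
                continue
            rows.append((peak_id, gid[best], signed))
    out = pd.DataFrame(rows, columns=["peak_id", "gene_id", "tss_distance"])
    out = out.set_index("peak_id")
    n_dropped = len(centers) - len(out)
    if n_dropped:
        import logging

        logging.getLogger("kbcomp").info(
            "annotate_nearest_gene: %d peak(s) left unannotated", n_dropped
        )
    return out


def reduce_best_peak_per_gene(
    annotated: pd.DataFrame, fc: pd.Series
) -> pd.DataFrame:
    """One row per gene keeping the annotated peak with maximal log2FC.

    Ties are broken by smaller |tss_distance|, then lexicographic peak_id.
    Returns a gene_id-indexed frame with best_peak_id, best_log2fc,
    tss_distance and n_peaks_annotated.
    """
    missing = annotated.index.difference(fc.index)
    if len(missing):
        raise ValidationError(f"fold change missing for peaks: {list(missing[:5])}")
    df = annotated.copy()
    df["log2fc"] = fc.reindex(df.index)
    df["abs_dist"] = df["tss_distance"].abs()
    df = df.reset_index(names="peak_id").sort_values(
        ["gene_id", "log2fc", "abs_dist", "peak_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    n_peaks = df.groupby("gene_id").size()
    best = df.drop_duplicates("gene_id", keep="first").set_index("gene_id")
    out = pd.DataFrame(
        {
            "best_peak_id": best["peak_id"],
            "best_log2fc": best["log2fc"],
            "tss_distance": best["tss_distance"],
            "n_peaks_annotated": n_peaks,
        }
    )
    return out.sort_index()


def mean_tss_distance(summaries: pd.DataFrame, gene_subset=None) -> float:
    """Arithmetic mean signed TSS distance over ``gene_subset`` (default:
    all summarized genes)."""
    d = summaries["tss_distance"]
    if gene_subset is not None:
        subset = pd.Index(sorted(gene_subset))
        missing = subset.difference(summaries.index)
        d = d.reindex(subset.intersection(summaries.index))
    if len(d) == 0:
        raise ValidationError("empty gene subset for mean TSS distance")
    return float(d.mean())
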