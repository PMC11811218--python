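"""Master peak set construction, RPKM quantification, fold changes and
binding filters.

Conventions carried throughout: all thresholds are strict inequalities
(RPKM > 10, log2FC > 1); fold changes are log2((a + p) / (b + p)) with a
pseudocount p (default 1 RPKM) so ratios stay defined at zero signal;
percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core_io import PeakTable, ValidationError


@dataclass(frozen=True)
class DistributionSummary:
    """Descriptive statistics of a log2 fold-change distribution."""

    n: int
    mean: float
    p10: float
    p90: float


def merge_master_peaks(peak_sets: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Union of interval sets with overlapping or book-ended intervals merged.

    Each input is a DataFrame with chrom/start/end columns (0-based
    half-open). Returns a sorted, disjoint master set with fresh peak_ids,
    mirroring the default behaviour of genome-arithmetic merge tools
    (intervals at distance 0 are joined).
    """
    frames = [df[["chrom", "start", "end"]] for df in peak_sets if len(df)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"]).set_axis(
            pd.Index([], name="peak_id"), axis=0
        )
    cat = pd.concat(frames, ignore_index=True)
    if (cat["start"] >= cat["end"]).any():
        raise ValidationError("empty or inverted interval in input set")
    cat = cat.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    for chrom, grp in cat.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out.index = pd.Index(
        [f"peak_{i + 1:06d}" for i in range(len(out))], name="peak_id"
    )
    return out


def compute_rpkm(
    read_counts: pd.DataFrame, peak_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """RPKM = count * 1e9 / (length_bp * library_size), element-wise."""
    lengths = peak_lengths.reindex(read_counts.index)
    libs = library_sizes.reindex(read_counts.columns)
    if (lengths <= 0).any():
        raise ValidationError("non-positive peak length")
    if libs.isna().any() or (libs <= 0).any():
        raise ValidationError("missing or non-positive library size")
    return read_counts * 1e9 / np.outer(lengths, libs)


def log2_fold_change(signal_a, signal_b, pseudocount: float = 1.0):
    """log2((a + p) / (b + p)); antisymmetric in (a, b).

    With p = 0 both signals must be strictly positive.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if pseudocount == 0 and (np.any(a <= 0) or np.any(b <= 0)):
        raise ValidationError("zero signal with pseudocount 0")
    fc = np.log2((a + pseudocount) / (b + pseudocount))
    if isinstance(signal_a, pd.Series):
        return pd.Series(fc, index=signal_a.index)
    return fc if fc.ndim else float(fc)


def filter_min_signal(
    table: PeakTable, threshold: float = 10.0, scope: str = "any_condition"
) -> PeakTable:
    """Keep peaks with signal strictly above ``threshold`` in any (default)
    or in all conditions."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if scope == "any_condition":
        keep = table.signal.max(axis=1) > threshold
    elif scope == "all_conditions":
        keep = table.signal.min(axis=1) > threshold
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return table.subset(table.signal.index[keep])


def select_induced_peaks(
    table: PeakTable,
    stimulated: str,
    unstimulated: str,
    min_log2fc: float = 1.0,
    pseudocount: float = 1.0,
) -> PeakTable:
    """Peaks whose stimulated/unstimulated log2FC is strictly above
    ``min_log2fc``; condition arguments are signal column labels."""
    for lab in (stimulated, unstimulated):
        if lab not in table.signal.columns:
            raise KeyError(f"condition {lab!r} not present in peak table")
    fc = log2_fold_change(
        table.signal[stimulated], table.signal[unstimulated], pseudocount
    )
    return table.subset(table.signal.index[fc > min_log2fc])


def summarize_distribution(fc) -> DistributionSummary:
    """Mean and 10th/90th percentiles (linear interpolation) of a
    fold-change vector."""
    values = np.asarray(fc, dtype=float)
    if values.size == 0:
        raise ValidationError("empty fold-change vector")
    return DistributionSummary(
        n=int(values.size),
        mean=float(values.mean()),
        p10=float(np.percentile(values, 10)),
        p90=float(np.percentile(values, 90)),
    )
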