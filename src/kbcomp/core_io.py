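"""Readers, writers and the validated in-memory data model.

All genomic coordinates inside the package are 0-based half-open (BED
convention). GTF input (1-based, closed) is converted on read: subtract 1
from the start coordinate only. Sample metadata is always an explicit
sample sheet (TSV) mapping matrix columns to experimental conditions;
condition labels are never parsed out of column-name strings.

Replicates, when present in a sample sheet, are collapsed to one column
per condition by arithmetic mean of the normalized signal (RPKM / CPM)
before any analysis.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("kbcomp")

# -- controlled vocabularies -------------------------------------------------

GENOTYPES = (
    "WT",
    "RelB_KO",       # RelB-/-
    "RelB_DB",       # RelB DNA-binding mutant (RelB^DB/DB)
    "IFNAR_KO",      # IFNAR-/-
    "IFNAR_RelB_KO",
    "IFNAR_RelB_DB",
)
STIMULI = ("none", "LPS", "CpG", "polyIC")
ASSAYS = ("RelA_ChIP", "RelB_ChIP", "RNA")

#: fixed decimal places used by every writer, so that write -> read -> write
#: is byte-identical.
FLOAT_DECIMALS = 6
FLOAT_FMT = f"%.{FLOAT_DECIMALS}f"


class FormatError(ValueError):
    """Malformed input file (structure, not values)."""


class ValidationError(ValueError):
    """Structurally sound input with invalid content."""


@dataclass(frozen=True, order=True)
class ConditionKey:
    """One experimental condition: genotype x stimulus x time x assay."""

    genotype: str
    stimulus: str
    time_h: float
    assay: str
    replicate: str | None = None

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if self.stimulus not in STIMULI:
            raise ValidationError(f"unknown stimulus {self.stimulus!r}")
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if self.time_h < 0:
            raise ValidationError(f"negative time {self.time_h}")

    def without_replicate(self) -> "ConditionKey":
        return replace(self, replicate=None)

    def label(self) -> str:
        t = f"{self.time_h:g}"
        base = f"{self.assay}:{self.genotype}:{self.stimulus}:{t}"
        return base if self.replicate is None else f"{base}:{self.replicate}"


def _match_conditions(
    conditions: dict[str, ConditionKey],
    genotype=None,
    stimulus=None,
    time_h=None,
    assay=None,
) -> list[str]:
    out = []
    for lab, key in conditions.items():
        if genotype is not None and key.genotype != genotype:
            continue
        if stimulus is not None and key.stimulus != stimulus:
            continue
        if time_h is not None and key.time_h != time_h:
            continue
        if assay is not None and key.assay != assay:
            continue
        out.append(lab)
    return out


# -- data containers ---------------------------------------------------------


@dataclass
class PeakTable:
    """Master peak intervals with per-condition binding signal (RPKM).

    ``peaks`` is indexed by peak_id with columns chrom/start/end; ``signal``
    shares the index and has one column per condition label. ``counts`` and
    ``library_sizes`` are optional raw material for RPKM recomputation.
    """

    peaks: pd.DataFrame
    signal: pd.DataFrame
    conditions: dict[str, ConditionKey]
    counts: pd.DataFrame | None = None
    library_sizes: pd.Series | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.peaks.index.has_duplicates:
            raise ValidationError("duplicate peak_id")
        if not (self.peaks["start"] < self.peaks["end"]).all():
            bad = self.peaks.index[self.peaks["start"] >= self.peaks["end"]]
            raise ValidationError(f"empty/inverted interval(s): {list(bad[:5])}")
        if not self.signal.index.equals(self.peaks.index):
            raise FormatError("signal rows do not match peak table rows")
        missing = set(self.signal.columns) ^ set(self.conditions)
        if missing:
            raise FormatError(f"signal columns/conditions mismatch: {sorted(missing)}")
        if (self.signal.to_numpy() < 0).any():
            raise ValidationError("negative signal values")

    @property
    def peak_lengths(self) -> pd.Series:
        return self.peaks["end"] - self.peaks["start"]

    @property
    def peak_centers(self) -> pd.Series:
        return (self.peaks["start"] + self.peaks["end"]) // 2

    def condition_label(self, genotype=None, stimulus=None, time_h=None, assay=None) -> str:
        hits = _match_conditions(self.conditions, genotype, stimulus, time_h, assay)
        if not hits:
            raise KeyError(
                f"no condition matching genotype={genotype} stimulus={stimulus} "
                f"time_h={time_h} assay={assay}"
            )
        if len(hits) > 1:
            raise KeyError(f"ambiguous condition query, matches {hits}")
        return hits[0]

    def subset(self, peak_ids) -> "PeakTable":
        idx = pd.Index(peak_ids)
        return PeakTable(
            peaks=self.peaks.loc[idx],
            signal=self.signal.loc[idx],
            conditions=dict(self.conditions),
            counts=None if self.counts is None else self.counts.loc[idx],
            library_sizes=self.library_sizes,
        )


@dataclass
class GeneAnnotationTable:
    """Gene TSS annotation; ``genes`` indexed by gene_id with
    gene_name / chrom / tss (0-based) / strand columns."""

    genes: pd.DataFrame

    def __post_init__(self):
        if self.genes.index.has_duplicates:
            raise ValidationError("duplicate gene_id in annotation")
        if not self.genes["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-' for every gene")


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts and CPM with sample metadata."""

    counts: pd.DataFrame
    cpm: pd.DataFrame
    conditions: dict[str, ConditionKey]
    gene_names: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.gene_names is None:
            self.gene_names = pd.Series("", index=self.counts.index)
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate gene_id")
        if self.counts.shape != self.cpm.shape:
            raise FormatError("counts and cpm dimensions differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        missing = set(self.cpm.columns) ^ set(self.conditions)
        if missing:
            raise FormatError(f"cpm columns/conditions mismatch: {sorted(missing)}")

    def condition_label(self, genotype=None, stimulus=None, time_h=None) -> str:
        hits = _match_conditions(self.conditions, genotype, stimulus, time_h, "RNA")
        if not hits:
            raise KeyError(
                f"no RNA condition matching genotype={genotype} "
                f"stimulus={stimulus} time_h={time_h}"
            )
        if len(hits) > 1:
            raise KeyError(f"ambiguous condition query, matches {hits}")
        return hits[0]


# -- sample sheets -----------------------------------------------------------


def read_sample_sheet(path) -> dict[str, ConditionKey]:
    """TSV with columns sample / genotype / stimulus / time_h / assay
    (+ optional replicate); returns column-name -> ConditionKey."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "genotype", "stimulus", "time_h", "assay"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet needs columns {sorted(required)}")
    out: dict[str, ConditionKey] = {}
    for _, row in df.iterrows():
        rep = row.get("replicate")
        rep = None if rep is None or pd.isna(rep) or rep == "" else str(rep)
        key = ConditionKey(
            genotype=row["genotype"],
            stimulus=row["stimulus"],
            time_h=float(row["time_h"]),
            assay=row["assay"],
            replicate=rep,
        )
        if row["sample"] in out:
            raise FormatError(f"duplicate sample name {row['sample']!r}")
        out[row["sample"]] = key
    keys = list(out.values())
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (genotype,stimulus,time,assay,replicate)")
    return out


def write_sample_sheet(conditions: dict[str, ConditionKey], path) -> None:
    rows = [
        {
            "sample": name,
            "genotype": k.genotype,
            "stimulus": k.stimulus,
            "time_h": f"{k.time_h:g}",
            "assay": k.assay,
            "replicate": "" if k.replicate is None else k.replicate,
        }
        for name, k in conditions.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _collapse_replicates(
    matrix: pd.DataFrame, samples: dict[str, ConditionKey]
) -> tuple[pd.DataFrame, dict[str, ConditionKey]]:
    """Average columns that share a condition once replicate ids are dropped."""
    groups: dict[ConditionKey, list[str]] = {}
    for name, key in samples.items():
        groups.setdefault(key.without_replicate(), []).append(name)
    cols, conditions = {}, {}
    for key, names in groups.items():
        lab = key.label()
        cols[lab] = matrix[names].mean(axis=1)
        conditions[lab] = key
    return pd.DataFrame(cols, index=matrix.index), conditions


# -- peak tables -------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """BED3+ -> DataFrame indexed by peak_id (column 4 when present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise FormatError("BED file needs at least 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
        }
    )
    if df.shape[1] >= 4:
        out.index = pd.Index(df[3].astype(str), name="peak_id")
    else:
        out.index = pd.Index(
            [f"peak_{i + 1:06d}" for i in range(len(out))], name="peak_id"
        )
    return out


def read_peak_table(
    bed_path,
    signal_path,
    sample_sheet,
    counts_path=None,
    library_sizes_path=None,
) -> PeakTable:
    """Assemble a validated PeakTable from a BED file, an RPKM signal TSV
    (first column peak_id) and a sample sheet."""
    peaks = read_bed(bed_path)
    signal = pd.read_csv(signal_path, sep="\t", index_col=0)
    signal.index = signal.index.astype(str)
    if len(signal) != len(peaks):
        raise FormatError(
            f"signal rows ({len(signal)}) do not match BED rows ({len(peaks)})"
        )
    if not signal.index.equals(peaks.index):
        if set(signal.index) != set(peaks.index):
            raise FormatError("signal peak_ids do not match BED peak_ids")
        signal = signal.loc[peaks.index]
    samples = read_sample_sheet(sample_sheet)
    chip = {n: k for n, k in samples.items() if k.assay != "RNA"}
    missing = set(signal.columns) - set(chip)
    if missing:
        raise FormatError(f"signal columns missing from sample sheet: {sorted(missing)}")
    signal = signal[[c for c in signal.columns if c in chip]]
    collapsed, conditions = _collapse_replicates(signal, chip)

    counts = lib = None
    if counts_path is not None:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        counts = counts.loc[peaks.index]
    if library_sizes_path is not None:
        lib = pd.read_csv(library_sizes_path, sep="\t", index_col=0).iloc[:, 0]
    return PeakTable(
        peaks=peaks, signal=collapsed, conditions=conditions,
        counts=counts, library_sizes=lib,
    )


def write_peak_table(pt: PeakTable, bed_path, signal_path, sample_sheet_path) -> None:
    bed = pt.peaks.copy()
    bed["name"] = bed.index
    bed["score"] = pt.signal.max(axis=1).map(lambda v: FLOAT_FMT % v)
    bed["strand"] = "."
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    pt.signal.to_csv(signal_path, sep="\t", index_label="peak_id", float_format=FLOAT_FMT)
    write_sample_sheet(pt.conditions, sample_sheet_path)


# -- expression --------------------------------------------------------------


def read_expression(
    counts_path, sample_sheet, non_integer="warn-round"
) -> ExpressionMatrix:
    """Counts TSV (gene_id index, optional gene_name column, one column per
    sample) + sample sheet -> ExpressionMatrix with CPM computed.

    ``non_integer``: "warn-round" (default) rounds fractional counts with a
    warning; "error" raises.
    """
    from .expression_programs import cpm_normalize

    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"empty counts file: {counts_path}")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise ValidationError("duplicate gene_id in counts file")
    gene_names = None
    if "gene_name" in df.columns:
        gene_names = df.pop("gene_name").fillna("").astype(str)
    counts = df.astype(float)
    if not np.allclose(counts.to_numpy() % 1.0, 0.0):
        if non_integer == "error":
            raise ValidationError("non-integer counts")
        logger.warning("non-integer counts in %s; rounding to nearest", counts_path)
        counts = counts.round()

    samples = read_sample_sheet(sample_sheet)
    rna = {n: k for n, k in samples.items() if k.assay == "RNA"}
    missing = set(counts.columns) - set(rna)
    if missing:
        raise FormatError(f"count columns missing from sample sheet: {sorted(missing)}")
    counts = counts[[c for c in counts.columns if c in rna]]
    cpm = cpm_normalize(counts)
    cpm_c, conditions = _collapse_replicates(cpm, rna)
    counts_c, _ = _collapse_replicates(counts, rna)
    return ExpressionMatrix(
        counts=counts_c, cpm=cpm_c, conditions=conditions, gene_names=gene_names
    )


def write_expression(
    expr: ExpressionMatrix, counts_path, sample_sheet_path
) -> None:
    out = expr.counts.copy()
    out.insert(0, "gene_name", expr.gene_names.reindex(out.index).fillna(""))
    out.to_csv(counts_path, sep="\t", index_label="gene_id", float_format="%.0f")
    write_sample_sheet(expr.conditions, sample_sheet_path)


# -- gene annotation ---------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _read_gtf(path, duplicate_policy="error") -> GeneAnnotationTable:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError("GTF line with fewer than 9 fields")
            if f[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            if "gene_id" not in attrs:
                raise FormatError("GTF gene line without gene_id attribute")
            strand = f[6]
            if strand not in ("+", "-"):
                raise ValidationError(f"missing/invalid strand for {attrs['gene_id']}")
            start1, end1 = int(f[3]), int(f[4])  # 1-based, closed
            tss = start1 - 1 if strand == "+" else end1 - 1  # 0-based
            rows.append(
                {
                    "gene_id": attrs["gene_id"],
                    "gene_name": attrs.get("gene_name", ""),
                    "chrom": f[0],
                    "tss": tss,
                    "strand": strand,
                }
            )
    df = pd.DataFrame(rows).set_index("gene_id")
    if df.index.has_duplicates:
        if duplicate_policy == "first":
            df = df[~df.index.duplicated(keep="first")]
        else:
            raise ValidationError("duplicate gene_id in GTF")
    return GeneAnnotationTable(df)


def _read_tss_tsv(path, duplicate_policy="error") -> GeneAnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"TSS TSV needs columns {sorted(required)}")
    if "gene_name" not in df.columns:
        df["gene_name"] = ""
    df["gene_name"] = df["gene_name"].fillna("").astype(str)
    df["tss"] = df["tss"].astype(int)
    df = df.set_index("gene_id")[["gene_name", "chrom", "tss", "strand"]]
    if df.index.has_duplicates and duplicate_policy == "first":
        df = df[~df.index.duplicated(keep="first")]
    return GeneAnnotationTable(df)


def read_annotation(path, duplicate_policy="error") -> GeneAnnotationTable:
    """Read a GTF (gene lines; 1-based closed, converted) or a TSS TSV
    (already 0-based) into a GeneAnnotationTable."""
    path = os.fspath(path)
    if path.endswith((".gtf", ".gff")):
        return _read_gtf(path, duplicate_policy)
    return _read_tss_tsv(path, duplicate_policy)


def write_annotation_tsv(ann: GeneAnnotationTable, path) -> None:
    ann.genes.to_csv(path, sep="\t", index_label="gene_id")


def write_annotation_gtf(ann: GeneAnnotationTable, path, gene_length=1000) -> None:
    """Emit one GTF gene line per gene; the gene body extends ``gene_length``
    bp downstream of the TSS (enough to round-trip the TSS and strand)."""
    with open(path, "w") as fh:
        for gid, row in ann.genes.iterrows():
            if row["strand"] == "+":
                start1 = row["tss"] + 1
                end1 = row["tss"] + gene_length
            else:
                start1 = max(1, row["tss"] + 1 - gene_length + 1)
                end1 = row["tss"] + 1
            attrs = f'gene_id "{gid}"; gene_name "{row["gene_name"]}";'
            fh.write(
                f'{row["chrom"]}\tkbcomp\tgene\t{start1}\t{end1}\t.\t'
                f'{row["strand"]}\t.\t{attrs}\n'
            )
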