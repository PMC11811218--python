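"""Synthetic ChIP-seq / RNA-seq dataset generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at a scale where every stage runs in seconds:

* a master peak set in which a subset of sites is RelB-bound and
  LPS-induced in WT, split into three planted RelA response behaviours in
  the RelB knockout (elevated / unchanged / reduced binding, planted mean
  log2FCs matching the three observed binding clusters);
* a gene x sample count matrix over six genotypes and a four-point CpG
  time course, with planted IFN-independent and IFN-dependent
  hyper-expression programs;
* promoter-proximal peak placement so that nearest-TSS annotation links
  each planted peak to its host gene, and a designated pro-inflammatory
  gene list whose binding sign is coupled to expression so the expected
  upper-right quadrant fraction equals ``planted_concordance``.

The three binding behaviours are separated in z-profile space by basal
occupancy structure, not only by the 1 h knockout/WT contrast: elevated
sites gain RelA in the knockout already at 0 h (RelB vacates the site),
reduced sites carry RelB-dependent basal RelA in WT. The knockout/WT
fold-change noise (``binding_noise_sd``) is therefore orthogonal to most
of the between-cluster geometry, which is what makes the planted labels
recoverable.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import (
    ConditionKey,
    ExpressionMatrix,
    GeneAnnotationTable,
    PeakTable,
    ValidationError,
    write_annotation_gtf,
    write_expression,
    write_peak_table,
)

CANONICAL_TIMES = (0.0, 1.0, 3.0, 8.0)

BINDING_CLUSTERS = ("elevated", "unchanged", "reduced")

# log2 offsets (relative to per-site baseline) of the mean RelA profile at
# (WT 0h, WT 1h, KO 0h, KO 1h); the KO 1h entry additionally receives the
# planted fold change.
_BINDING_PATTERNS = {
    "elevated": (0.0, 2.0, 1.5, 2.0),
    "unchanged": (0.0, 2.0, 0.0, 2.0),
    "reduced": (1.0, 2.0, 0.0, 2.0),
}

# genotype effect profiles (multiplier vs WT at the same time point) on the
# canonical 0/1/3/8 h grid; `E8` marks the configured peak hyper-effect.
_PROGRAM_EFFECTS = {
    "WT": (1.0, 1.0, 1.0, 1.0),
    "RelB_KO": (1.2, 1.5, "E8*0.95", "E8"),
    "RelB_DB": (1.1, 1.3, 1.4, 1.5),
    "IFNAR_KO": (1.0, 1.1, 1.2, 1.25),
    "IFNAR_RelB_KO": (1.2, 1.6, 1.8, 1.9),
    "IFNAR_RelB_DB": (1.15, 1.5, 1.7, 1.8),
}
_ISG_EFFECTS = {
    "WT": (1.0, 1.0, 1.0, 1.0),
    "RelB_KO": (1.15, 1.4, "ISG_PEAK", 1.45),
    "RelB_DB": (1.1, 1.35, 1.8, 1.4),
    "IFNAR_KO": (1.0, 0.8, 0.6, 0.55),
    "IFNAR_RelB_KO": (1.0, 0.8, 0.6, 0.55),
    "IFNAR_RelB_DB": (1.0, 0.8, 0.6, 0.55),
}

_WT_SHAPES = {
    "program": (1.0, 3.0, 8.0, 12.0),
    "isg": (1.0, 2.0, 10.0, 6.0),
    "background": (1.0, 1.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """All planted parameters; defaults are the study-scale conditions."""

    seed: int = 0
    # binding side
    n_peaks_per_cluster: tuple[int, int, int] = (1580, 2135, 719)
    planted_binding_log2fc: tuple[float, float, float] = (0.53, -0.08, -1.09)
    binding_noise_sd: float = 0.3     # log2 units, knockout/WT contrast
    cell_noise_sd: float = 0.05       # log2 units, per-cell technical noise
    n_background_peaks: int = 20000
    background_fc_mean: float = -0.03
    background_fc_sd: float = 0.53
    relb_induction_log2: float = 2.0
    # expression side
    n_genes: int = 15000
    n_program_genes: int = 117        # designated pro-inflammatory list
    n_ifn_independent_genes: int = 178
    n_ifn_dependent_genes: int = 93
    n_induced_other_genes: int = 800
    n_unnamed_genes: int = 25
    planted_concordance: float = 0.84
    expression_effect_fc: float = 1.5
    hyper_margin: float = 1.2         # peak effect = effect_fc * margin
    isg_peak_effect: float = 1.9
    expr_noise_sd: float = 0.05       # log2, per gene x sample
    library_size: int = 20_000_000
    nb_dispersion: float = 0.0        # 0 -> Poisson counts
    time_grid: tuple[float, ...] = CANONICAL_TIMES
    chip_stimulus: str = "LPS"
    expr_stimulus: str = "CpG"
    # genome layout
    n_chromosomes: int = 4
    gene_spacing: int = 50_000
    tss_offset_mean: float = -1352.0
    tss_offset_sd: float = 600.0

    def validate(self) -> None:
        n_elev, n_unch, n_red = self.n_peaks_per_cluster
        if min(self.n_peaks_per_cluster) < 0 or sum(self.n_peaks_per_cluster) < 1:
            raise ValidationError("need at least one planted peak")
        if not 0.0 <= self.planted_concordance <= 1.0:
            raise ValidationError("planted_concordance must be in [0, 1]")
        if self.binding_noise_sd < 0 or self.expr_noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")
        if self.planted_binding_log2fc[0] <= 0 and self.planted_concordance > 0:
            raise ValidationError(
                "infeasible concordance: elevated-binding effect must be positive "
                "to plant upper-right quadrant genes"
            )
        if self.expression_effect_fc * self.hyper_margin <= self.expression_effect_fc:
            raise ValidationError(
                "infeasible planting: hyper_margin must exceed 1 so measured fold "
                "changes clear the strict selection threshold"
            )
        if self.n_program_genes > self.n_ifn_independent_genes:
            raise ValidationError("program genes must fit in the IFN-independent set")
        need_elev = n_elev < self.n_ifn_independent_genes and self.planted_concordance > 0
        need_unch = n_unch < self.n_ifn_independent_genes and self.planted_concordance < 1
        if need_elev or need_unch:
            raise ValidationError(
                "elevated/unchanged cluster sizes must accommodate the "
                "IFN-independent genes (their peaks are drawn from both)"
            )
        hosts_needed = (
            sum(self.n_peaks_per_cluster)
            - self.n_ifn_independent_genes
            + self.n_ifn_independent_genes
            + self.n_ifn_dependent_genes
            + int(np.ceil(self.n_background_peaks / 2))
        )
        if self.n_genes < hosts_needed:
            raise ValidationError(
                f"n_genes={self.n_genes} too small to host all peaks "
                f"(need >= {hosts_needed})"
            )
        if min(self.time_grid) != 0:
            raise ValidationError("time grid must include the 0 h control")


@dataclass
class GroundTruth:
    """Planted labels and parameters, consistent with the emitted data."""

    peak_cluster: pd.Series                 # peak_id -> behaviour / background
    planted_binding_log2fc: pd.Series       # planted peaks only
    peak_host_gene: pd.Series               # peak_id -> intended gene
    gene_class: pd.Series                   # gene_id -> program/isg/...
    program_genes: list[str]                # designated pro-inflammatory list
    ifn_independent_genes: list[str]
    ifn_dependent_genes: list[str]
    induced_genes: list[str]
    hyper_genes: list[str]
    concordant: pd.Series                   # IFN-independent genes -> bool
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore


@dataclass
class SyntheticDataset:
    peaks: PeakTable
    expression: ExpressionMatrix
    annotation: GeneAnnotationTable
    truth: GroundTruth


def _interp_profile(times, canonical) -> np.ndarray:
    return np.interp(times, CANONICAL_TIMES, np.asarray(canonical, dtype=float))


def _effect_profile(spec_row, times, e8: float, isg_peak: float) -> np.ndarray:
    vals = [
        e8 * 0.95 if v == "E8*0.95" else e8 if v == "E8"
        else isg_peak if v == "ISG_PEAK" else float(v)
        for v in spec_row
    ]
    return _interp_profile(times, vals)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Deterministic (seeded) synthetic dataset with planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _generate_genes(config, rng)
    peaks, truth_bits = _generate_peaks(config, rng, genes)
    expression = _generate_expression(config, rng, genes)
    cls = genes["cls"]
    program_mask = cls == "program"
    ifn_ind = list(genes.index[program_mask])
    ifn_dep = list(genes.index[cls == "isg"])
    induced = list(genes.index[cls.isin(["program", "isg", "induced_other"])])
    truth = GroundTruth(
        peak_cluster=truth_bits["cluster"],
        planted_binding_log2fc=truth_bits["fc"],
        peak_host_gene=truth_bits["host"],
        gene_class=cls.copy(),
        program_genes=list(genes.index[genes["is_program"]]),
        ifn_independent_genes=ifn_ind,
        ifn_dependent_genes=ifn_dep,
        induced_genes=induced,
        hyper_genes=ifn_ind + ifn_dep,
        concordant=truth_bits["concordant"],
        config=config,
    )
    annotation = GeneAnnotationTable(
        genes[["gene_name", "chrom", "tss", "strand"]].copy()
    )
    return SyntheticDataset(peaks=peaks, expression=expression,
                            annotation=annotation, truth=truth)


# -- genes -------------------------------------------------------------------


def _generate_genes(config: SyntheticConfig, rng) -> pd.DataFrame:
    n = config.n_genes
    per_chrom = int(np.ceil(n / config.n_chromosomes))
    idx = np.arange(n)
    chrom = np.array([f"chr{i // per_chrom + 1}" for i in idx])
    slot = idx % per_chrom
    tss = slot * config.gene_spacing + config.gene_spacing // 2
    strand = rng.choice(["+", "-"], size=n)

    cls = np.full(n, "background", dtype=object)
    order = rng.permutation(n)
    k = 0
    for name, count in (
        ("program", config.n_ifn_independent_genes),
        ("isg", config.n_ifn_dependent_genes),
        ("induced_other", config.n_induced_other_genes),
    ):
        cls[order[k:k + count]] = name
        k += count
    is_program = np.zeros(n, dtype=bool)
    is_program[order[: config.n_program_genes]] = True

    gene_ids = [f"g{i + 1:05d}" for i in idx]
    names = np.array([f"Syn{i + 1:05d}" for i in idx], dtype=object)
    bg_positions = order[k:]
    unnamed = bg_positions[: min(config.n_unnamed_genes, len(bg_positions))]
    names[unnamed] = ""

    return pd.DataFrame(
        {
            "gene_name": names,
            "chrom": chrom,
            "tss": tss,
            "strand": strand,
            "cls": cls,
            "is_program": is_program,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


# -- peaks -------------------------------------------------------------------


def _chip_conditions(config) -> dict[str, ConditionKey]:
    keys = []
    for assay in ("RelA_ChIP", "RelB_ChIP"):
        for genotype in ("WT", "RelB_KO"):
            keys.append(ConditionKey(genotype, "none", 0.0, assay))
            keys.append(ConditionKey(genotype, config.chip_stimulus, 1.0, assay))
    return {k.label(): k for k in keys}


def _generate_peaks(config: SyntheticConfig, rng, genes: pd.DataFrame):
    spacing = config.gene_spacing
    sd, cell_sd = config.binding_noise_sd, config.cell_noise_sd
    effects = dict(zip(BINDING_CLUSTERS, config.planted_binding_log2fc))

    program_mask = genes["cls"] == "program"
    program_ids = list(genes.index[program_mask])
    other_ids = list(genes.index[genes["cls"] == "induced_other"])
    bg_ids = list(genes.index[genes["cls"] == "background"])

    # planted peaks at the IFN-independent genes: sign-controlled so the
    # upper-right fraction equals planted_concordance. Exactly round(p * n)
    # genes are made concordant within the designated program list and
    # within the remainder (the observed quantity is a realized count, so
    # exact allocation rather than independent coins keeps the planted
    # fraction free of binomial drift).
    host, cluster, fc = [], [], []
    coin_by_gene = {}
    for group_mask in (genes["is_program"], program_mask & ~genes["is_program"]):
        ids = list(genes.index[group_mask])
        n_conc = int(round(config.planted_concordance * len(ids)))
        flags = np.zeros(len(ids), dtype=bool)
        flags[:n_conc] = True
        coin_by_gene.update(zip(ids, rng.permutation(flags)))
    coin = [coin_by_gene[g] for g in program_ids]
    concordant = []
    for gid, conc in zip(program_ids, coin):
        host.append(gid)
        concordant.append(bool(conc))
        # a 0.2 log2 sign margin keeps the planted quadrant identifiable
        # under per-cell measurement noise (sd ~ cell_noise_sd * sqrt(2))
        if conc:
            cluster.append("elevated")
            fc.append(max(abs(rng.normal(effects["elevated"], sd)), 0.2))
        else:
            cluster.append("unchanged")
            fc.append(min(-abs(rng.normal(effects["unchanged"], sd)), -0.2))
    concordant = pd.Series(concordant, index=pd.Index(program_ids, name="gene_id"))

    # remaining planted peaks on induced-other, then background genes
    consumed = pd.Series(cluster).value_counts()
    remaining = []
    for name, count in zip(BINDING_CLUSTERS, config.n_peaks_per_cluster):
        remaining += [name] * (count - int(consumed.get(name, 0)))
    remaining = list(rng.permutation(remaining)) if remaining else []
    extra_hosts = (other_ids + bg_ids)[: len(remaining)]
    bg_peak_hosts = [g for g in bg_ids if g not in set(extra_hosts)]
    for gid, name in zip(extra_hosts, remaining):
        host.append(gid)
        cluster.append(name)
        fc.append(rng.normal(effects[name], sd))

    n_planted = len(host)
    fc = np.asarray(fc, dtype=float)
    cluster = np.asarray(cluster, dtype=object)

    # planted RelA profiles
    b = np.clip(rng.normal(np.log2(30), 1.0, n_planted), np.log2(3), None)
    pat = np.array([_BINDING_PATTERNS[c] for c in cluster])  # n x 4
    log2rpkm = b[:, None] + pat
    log2rpkm[:, 3] += fc - 0.0  # KO 1h carries the planted fold change
    log2rpkm += rng.normal(0.0, cell_sd, size=log2rpkm.shape)
    # planted RelB profiles: pre-bound in WT, induced by stimulation
    bR = np.clip(rng.normal(np.log2(8), 1.0, n_planted), np.log2(3), None)
    relb_wt0 = bR + rng.normal(0.0, cell_sd, n_planted)
    relb_wt1 = (
        bR + config.relb_induction_log2 + rng.normal(0.0, 0.25, n_planted)
    )
    relb_ko = rng.normal(np.log2(0.2), 0.5, size=(n_planted, 2))

    # background peaks
    n_bg = config.n_background_peaks
    bb = rng.normal(np.log2(30), 1.2, n_bg)
    bg_wt1 = bb + rng.normal(0.0, 0.2, n_bg)
    bg_wt0 = bb - np.maximum(0.0, rng.normal(0.5, 0.5, n_bg))
    bg_fc = rng.normal(config.background_fc_mean, config.background_fc_sd, n_bg)
    bg_ko1 = bg_wt1 + bg_fc
    bg_ko0 = bg_wt0 + rng.normal(0.0, 0.2, n_bg)
    bg_relb = rng.normal(np.log2(1.5), 0.7, n_bg)
    bg_relb_wt0 = bg_relb
    bg_relb_wt1 = bg_relb + rng.normal(0.0, 0.2, n_bg)
    bg_relb_ko = rng.normal(np.log2(0.2), 0.5, size=(n_bg, 2))

    # positions: planted peaks promoter-proximal on their host gene; the
    # designated program genes use the configured TSS-offset distribution
    hosts_frame = genes.loc[host]
    is_prog_host = hosts_frame["cls"].to_numpy() == "program"
    off = np.where(
        is_prog_host,
        rng.normal(config.tss_offset_mean, config.tss_offset_sd, n_planted),
        rng.normal(-800.0, 3000.0, n_planted),
    )
    off = np.clip(off, -0.4 * spacing, 0.4 * spacing)
    widths = rng.integers(300, 900, n_planted)
    sign = np.where(hosts_frame["strand"].to_numpy() == "+", 1, -1)
    centers = hosts_frame["tss"].to_numpy() + sign * off.astype(int)
    starts = np.maximum(0, centers.astype(int) - widths // 2)
    ends = starts + widths

    # background peaks: up to two per non-host background gene, placed in
    # disjoint flanks so they never overlap
    bg_host, bg_off = [], []
    for i in range(n_bg):
        gid = bg_peak_hosts[i // 2] if bg_peak_hosts else bg_ids[i % len(bg_ids)]
        bg_host.append(gid)
        if i % 2 == 0:
            bg_off.append(rng.uniform(-0.3 * spacing, -0.02 * spacing))
        else:
            bg_off.append(rng.uniform(0.02 * spacing, 0.3 * spacing))
    if n_bg:
        bgf = genes.loc[bg_host]
        bg_sign = np.where(bgf["strand"].to_numpy() == "+", 1, -1)
        bg_centers = bgf["tss"].to_numpy() + bg_sign * np.asarray(bg_off, dtype=int)
        bg_widths = rng.integers(300, 900, n_bg)
        bg_starts = np.maximum(0, bg_centers.astype(int) - bg_widths // 2)
        bg_ends = bg_starts + bg_widths

    cond = _chip_conditions(config)
    labels = {  # column label per (assay, genotype, time)
        (k.assay, k.genotype, k.time_h): lab for lab, k in cond.items()
    }
    stim = config.chip_stimulus

    def cols(rela4, relb4):
        return {
            labels[("RelA_ChIP", "WT", 0.0)]: rela4[:, 0],
            labels[("RelA_ChIP", "WT", 1.0)]: rela4[:, 1],
            labels[("RelA_ChIP", "RelB_KO", 0.0)]: rela4[:, 2],
            labels[("RelA_ChIP", "RelB_KO", 1.0)]: rela4[:, 3],
            labels[("RelB_ChIP", "WT", 0.0)]: relb4[:, 0],
            labels[("RelB_ChIP", "WT", 1.0)]: relb4[:, 1],
            labels[("RelB_ChIP", "RelB_KO", 0.0)]: relb4[:, 2],
            labels[("RelB_ChIP", "RelB_KO", 1.0)]: relb4[:, 3],
        }

    planted_sig = cols(
        2.0 ** log2rpkm,
        2.0 ** np.column_stack([relb_wt0, relb_wt1, relb_ko]),
    )
    frames = [
        pd.DataFrame(
            {"chrom": hosts_frame["chrom"].to_numpy(), "start": starts, "end": ends}
            | planted_sig
        )
    ]
    meta = [
        pd.DataFrame(
            {"cluster": cluster, "fc": fc, "host": host}
        )
    ]
    if n_bg:
        bg_sig = cols(
            2.0 ** np.column_stack([bg_wt0, bg_wt1, bg_ko0, bg_ko1]),
            2.0 ** np.column_stack([bg_relb_wt0, bg_relb_wt1, bg_relb_ko]),
        )
        frames.append(
            pd.DataFrame(
                {"chrom": bgf["chrom"].to_numpy(), "start": bg_starts, "end": bg_ends}
                | bg_sig
            )
        )
        meta.append(
            pd.DataFrame(
                {"cluster": "background", "fc": np.nan, "host": bg_host}
            )
        )
    allp = pd.concat(frames, ignore_index=True)
    allm = pd.concat(meta, ignore_index=True)
    order = allp.sort_values(["chrom", "start", "end"], kind="mergesort").index
    allp = allp.loc[order].reset_index(drop=True)
    allm = allm.loc[order].reset_index(drop=True)
    peak_ids = pd.Index(
        [f"p{i + 1:06d}" for i in range(len(allp))], name="peak_id"
    )
    allp.index = peak_ids
    allm.index = peak_ids

    signal = allp[list(cond)]
    peaks_bed = allp[["chrom", "start", "end"]]
    lengths = peaks_bed["end"] - peaks_bed["start"]
    libs = pd.Series(
        (config.library_size * rng.uniform(0.8, 1.2, len(cond))).round(),
        index=list(cond),
    )
    counts = (signal * np.outer(lengths, libs) / 1e9).round()

    table = PeakTable(
        peaks=peaks_bed, signal=signal, conditions=cond,
        counts=counts, library_sizes=libs,
    )
    planted_mask = allm["cluster"] != "background"
    bits = {
        "cluster": allm["cluster"],
        "fc": allm.loc[planted_mask, "fc"],
        "host": allm["host"],
        "concordant": concordant,
    }
    return table, bits


# -- expression --------------------------------------------------------------


def _rna_conditions(config) -> dict[str, ConditionKey]:
    keys = []
    for genotype in (
        "WT", "RelB_KO", "RelB_DB", "IFNAR_KO", "IFNAR_RelB_KO", "IFNAR_RelB_DB"
    ):
        for t in config.time_grid:
            stimulus = "none" if t == 0 else config.expr_stimulus
            keys.append(ConditionKey(genotype, stimulus, float(t), "RNA"))
    return {k.label(): k for k in keys}


def _generate_expression(config: SyntheticConfig, rng, genes: pd.DataFrame):
    from .expression_programs import cpm_normalize

    cond = _rna_conditions(config)
    times = np.asarray(config.time_grid, dtype=float)
    n, cls = len(genes), genes["cls"].to_numpy()
    e8 = config.expression_effect_fc * config.hyper_margin

    cpm0 = np.empty(n)
    # background genes carry most of the library mass (housekeeping-like),
    # so induced programs stay a few percent of each column and CPM
    # renormalization barely perturbs planted between-genotype ratios
    for name, median, sd_log2, floor in (
        ("program", 20.0, 1.0, 5.0),
        ("isg", 20.0, 1.0, 5.0),
        ("induced_other", 10.0, 1.0, 4.0),
        ("background", 40.0, 1.5, 0.01),
    ):
        m = cls == name
        cpm0[m] = np.maximum(
            floor, 2.0 ** rng.normal(np.log2(median), sd_log2, int(m.sum()))
        )

    # WT induction shapes (genes x times)
    shapes = np.ones((n, len(times)))
    for name in ("program", "isg", "background"):
        m = cls == name
        shapes[m] = _interp_profile(times, _WT_SHAPES[name])
    m = cls == "induced_other"
    n_other = int(m.sum())
    if n_other:
        peak_fold = 2.0 ** rng.uniform(2.0, 3.5, n_other)
        stim_idx = np.flatnonzero(times > 0)
        peak_pos = rng.choice(stim_idx, n_other)
        prof = np.ones((n_other, len(times)))
        prof[:, stim_idx] = np.sqrt(peak_fold)[:, None]
        prof[np.arange(n_other), peak_pos] = peak_fold
        shapes[m] = prof

    effect_tables = {
        "program": {
            g: _effect_profile(v, times, e8, config.isg_peak_effect)
            for g, v in _PROGRAM_EFFECTS.items()
        },
        "isg": {
            g: _effect_profile(v, times, e8, config.isg_peak_effect)
            for g, v in _ISG_EFFECTS.items()
        },
    }

    targets = {}
    for lab, key in cond.items():
        ti = int(np.flatnonzero(times == key.time_h)[0])
        mult = np.ones(n)
        for name, table in effect_tables.items():
            mcls = cls == name
            mult[mcls] = table[key.genotype][ti]
        noise = 2.0 ** rng.normal(0.0, config.expr_noise_sd, n)
        targets[lab] = cpm0 * shapes[:, ti] * mult * noise
    target = pd.DataFrame(targets, index=genes.index)
    target = target * 1e6 / target.sum(axis=0)

    libs = (config.library_size * rng.uniform(0.8, 1.2, len(cond))).round()
    lam = target.to_numpy() * libs[None, :] / 1e6
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, lam / shape)
    counts = pd.DataFrame(
        rng.poisson(lam).astype(float), index=genes.index, columns=list(cond)
    )
    cpm = cpm_normalize(counts)
    return ExpressionMatrix(
        counts=counts, cpm=cpm, conditions=cond,
        gene_names=genes["gene_name"].copy(),
    )


# -- fixtures ----------------------------------------------------------------

FIXTURE_FILES = {
    "bed": "peaks.bed",
    "signal": "chip_rpkm.tsv",
    "chip_counts": "chip_counts.tsv",
    "chip_libs": "chip_library_sizes.tsv",
    "chip_samples": "chip_samples.tsv",
    "rna_counts": "expression_counts.tsv",
    "rna_samples": "rna_samples.tsv",
    "gtf": "genes.gtf",
    "truth": "ground_truth.json",
}


def write_fixture(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Emit the dataset as the plain-text file set core_io reads back."""
    os.makedirs(out_dir, exist_ok=True)
    p = {k: os.path.join(out_dir, v) for k, v in FIXTURE_FILES.items()}
    write_peak_table(dataset.peaks, p["bed"], p["signal"], p["chip_samples"])
    if dataset.peaks.counts is not None:
        dataset.peaks.counts.to_csv(
            p["chip_counts"], sep="\t", index_label="peak_id", float_format="%.0f"
        )
        dataset.peaks.library_sizes.rename("library_size").to_csv(
            p["chip_libs"], sep="\t", index_label="sample", float_format="%.0f"
        )
    write_expression(dataset.expression, p["rna_counts"], p["rna_samples"])
    write_annotation_gtf(dataset.annotation, p["gtf"])
    t = dataset.truth
    payload = {
        "peak_cluster": t.peak_cluster.to_dict(),
        "planted_binding_log2fc": t.planted_binding_log2fc.to_dict(),
        "peak_host_gene": t.peak_host_gene.to_dict(),
        "gene_class": t.gene_class.to_dict(),
        "program_genes": t.program_genes,
        "ifn_independent_genes": t.ifn_independent_genes,
        "ifn_dependent_genes": t.ifn_dependent_genes,
        "induced_genes": t.induced_genes,
        "hyper_genes": t.hyper_genes,
        "concordant": {k: bool(v) for k, v in t.concordant.to_dict().items()},
        "config": asdict(t.config),
    }
    with open(p["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return p


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    cfg_dict = d["config"]
    for key in ("n_peaks_per_cluster", "planted_binding_log2fc", "time_grid"):
        cfg_dict[key] = tuple(cfg_dict[key])
    return GroundTruth(
        peak_cluster=pd.Series(d["peak_cluster"]),
        planted_binding_log2fc=pd.Series(d["planted_binding_log2fc"]),
        peak_host_gene=pd.Series(d["peak_host_gene"]),
        gene_class=pd.Series(d["gene_class"]),
        program_genes=d["program_genes"],
        ifn_independent_genes=d["ifn_independent_genes"],
        ifn_dependent_genes=d["ifn_dependent_genes"],
        induced_genes=d["induced_genes"],
        hyper_genes=d["hyper_genes"],
        concordant=pd.Series(d["concordant"]),
        config=SyntheticConfig(**cfg_dict),
    )
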