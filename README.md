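# kbcomp

Integrative ChIP-seq/RNA-seq analysis of NF-κB subunit competition at κB
sites, for regulatory genomicists studying how the RelB subunit restrains
RelA-driven inflammatory transcription in dendritic cells.

## The analysis

In wild-type dendritic cells, RelB occupies a subset of genomic κB sites.
The hypothesis the pipeline quantifies is competitive: when RelB is lost
(knockout, or a DNA-binding-dead mutant), RelA gains access to those
sites and the genes they regulate become hyper-expressed. The pipeline
measures each link of that chain:

1. **Binding quantification.** Peaks from all ChIP samples are merged
   into one master set (union, book-ended intervals joined); per-peak
   binding is RPKM = reads·10⁹ / (peak length · library size). Peaks are
   kept when RPKM > 10 in any condition (strict), and the knockout/WT
   RelA change is log₂FC = log₂((RPKM_KO + p)/(RPKM_WT + p)) with
   pseudocount p = 1.
2. **Binding-pattern clusters.** Sites with stimulus-induced RelB binding
   in WT (log₂FC > 1 at 1 h) are clustered by k-means (k = 3) on their
   row-z-scored RelA profile over the genotype × time grid, giving
   elevated (A) / unchanged (B) / reduced (C) RelA responses to RelB
   loss, each summarized by its mean knockout/WT log₂FC.
3. **Peak-gene linking.** Every peak is annotated to the gene with the
   nearest TSS (signed, strand-aware distance; negative = upstream), then
   reduced to one peak per gene by maximal log₂FC.
4. **Expression programs.** RNA-seq counts are CPM-normalized
   (column sums 10⁶); genes induced by stimulation (log₂FC > 1 vs 0 h, in
   WT or knockout) and hyper-expressed in the knockout (FC > 1.5 at any
   time, on pseudocounted CPM) are split by k-means (k = 2) on z-scored
   CPM into an IFN-independent program (A) and an IFN-dependent program
   (B, collapsing in IFNAR⁻/⁻ backgrounds).
5. **Integration.** Per gene, binding change (RelA, 1 h LPS) is joined
   with expression change (8 h CpG); the concordance of a designated
   pro-inflammatory gene list is the fraction in the upper-right quadrant
   (both log₂FC > 0), and binding at hyper-expressed vs
   expression-unchanged genes (−0.1 < log₂FC < 0.1 at 8 h) is compared
   with Welch's t (Mann-Whitney as alternative).

A seeded synthetic-data generator (`kbcomp.synthetic`) emits peak tables,
count matrices and annotation with planted ground truth for every stage,
so the whole pipeline is validated without external downloads.

## Worked example

```python
from kbcomp import SyntheticConfig, generate_dataset, run_analysis

ds = generate_dataset(SyntheticConfig(seed=0))     # study-scale defaults
res = run_analysis(ds.peaks, ds.expression, ds.annotation,
                   program_genes=ds.truth.program_genes)
r = res.report
print(r["peak_fc_distribution"])
print(r["peak_clusters"])
print(r["n_hyperexpressed_genes"], r["gene_clusters"])
print(r["concordance"], round(r["mean_tss_distance_bp"], 1))
```

prints (seed 0):

```
{'n': 22933, 'mean': -0.0176..., 'p10': -0.7099..., 'p90': 0.6611...}
[{'cluster': 'A', 'n': 1633, 'mean_log2fc': 0.5377...},
 {'cluster': 'B', 'n': 2059, 'mean_log2fc': -0.0820...},
 {'cluster': 'C', 'n': 741, 'mean_log2fc': -1.0765...}]
271 {'A': 178, 'B': 93}
{'n_total': 117, 'n_upper_right': 98, 'fraction': 0.8376...} -1330.4
```

Reading: the genome-wide RelA knockout/WT log₂FC distribution is centred
near zero (most binding is unaffected by RelB loss), but at induced
RelB-bound sites three response patterns emerge, the elevated cluster
gaining ~0.54 log₂ units of RelA binding. 271 genes are stimulus-induced
and knockout-hyper-expressed, splitting 178 IFN-independent / 93
IFN-dependent, and 98 of the 117 designated pro-inflammatory genes
(83.8%) show both elevated binding and elevated expression, with their
best peaks centred ~1.3 kb upstream of the TSS.

The same analysis runs from the shell on the plain-text formats:

```sh
kbcomp simulate --seed 0 --out fixtures/
kbcomp run --config pipeline.yaml      # paths + thresholds in YAML
```

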