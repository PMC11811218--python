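import numpy as np
import pandas as pd
import pytest

from kbcomp import (
    ValidationError,
    cluster_gene_programs,
    cpm_normalize,
    expression_log2fc,
    program_fold_differences,
    select_hyperexpressed,
    select_induced_genes,
    select_programs,
    select_unchanged,
)
from kbcomp.binding_clusters import ClusterAssignment

from conftest import expression_from_cpm, rna_key


class TestCpmNormalize:
    def test_known_columns(self):
        counts = pd.DataFrame({"s": [1.0, 9.0]}, index=["a", "b"])
        out = cpm_normalize(counts)
        assert list(out["s"]) == [100_000.0, 900_000.0]
        flat = cpm_normalize(pd.DataFrame({"s": [5.0] * 4}, index=list("abcd")))
        assert np.allclose(flat["s"], 1e6 / 4)

    def test_columns_sum_to_1e6(self):
        rng = np.random.default_rng(21)
        counts = pd.DataFrame(rng.integers(0, 1000, (30, 5)).astype(float) + 1)
        assert np.allclose(cpm_normalize(counts).sum(axis=0), 1e6, atol=1e-6)

    def test_zero_library_rejected(self):
        with pytest.raises(ValidationError):
            cpm_normalize(pd.DataFrame({"s": [0.0, 0.0]}))


class TestExpressionLog2fc:
    @pytest.mark.parametrize("a, b, expected", [(3, 1, 1.0), (7, 7, 0.0), (0, 0, 0.0)])
    def test_pseudocounted_values(self, a, b, expected):
        assert expression_log2fc(a, b) == pytest.approx(expected)


def _two_genotype_expr(wt, ko, gene_names=None, times=(0, 1, 3, 8)):
    """wt/ko: gene -> list of CPM per time point."""
    genes = list(wt)
    keys = [rna_key("WT", t) for t in times] + [rna_key("RelB_KO", t) for t in times]
    data = np.array([list(wt[g]) + list(ko[g]) for g in genes], dtype=float)
    cpm = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    return expression_from_cpm(cpm, keys, gene_names)


class TestSelections:
    def test_induced_gene_and_strict_boundary(self):
        wt = {"ga": [10, 10, 50, 10],   # log2(51/11) = 2.21 -> induced
              "gb": [9, 19, 9, 9],      # log2(20/10) = 1 exactly -> excluded
              "gc": [9, 20, 9, 9]}      # log2(21/10) > 1 -> induced
        expr = _two_genotype_expr(wt, wt)
        out = select_induced_genes(expr, ["WT"], "CpG")
        assert out == {"ga", "gc"}

    def test_empty_gene_name_removed_regardless_of_fc(self):
        wt = {"ga": [10, 100, 100, 100], "gb": [10, 100, 100, 100]}
        names = pd.Series({"ga": "Gene", "gb": ""})
        expr = _two_genotype_expr(wt, wt, gene_names=names)
        assert select_induced_genes(expr, ["WT"], "CpG") == {"ga"}

    def test_union_over_genotypes(self):
        wt = {"ga": [10, 10, 10, 10]}
        ko = {"ga": [10, 10, 60, 10]}  # induced only in the knockout
        expr = _two_genotype_expr(wt, ko)
        assert select_induced_genes(expr, ["WT"], "CpG") == set()
        assert select_induced_genes(expr, ["WT", "RelB_KO"], "CpG") == {"ga"}

    def test_hyperexpressed_strict_boundary(self):
        wt = {"ga": [19, 19, 19, 19], "gb": [19, 19, 19, 19]}
        ko = {"ga": [19, 19, 19, 29],  # 30/20 = 1.5 exactly -> excluded
              "gb": [19, 19, 19, 35]}  # 36/20 = 1.8 -> included
        expr = _two_genotype_expr(wt, ko)
        out = select_hyperexpressed(expr, "RelB_KO", "WT", "CpG",
                                    within={"ga", "gb"})
        assert out == {"gb"}

    def test_hyper_selection_monotone_in_threshold(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(60)]
        wt = {g: rng.uniform(5, 50, 4) for g in genes}
        ko = {g: wt[g] * rng.uniform(0.5, 3.0) for g in genes}
        expr = _two_genotype_expr(wt, ko)
        lo = select_hyperexpressed(expr, "RelB_KO", "WT", "CpG", min_fc=1.2)
        hi = select_hyperexpressed(expr, "RelB_KO", "WT", "CpG", min_fc=2.0)
        assert hi <= lo

    def test_unchanged_open_interval(self):
        # the band is open: a gene sitting exactly on the edge is excluded
        # (edge chosen at an exactly representable log2FC of 1.0)
        wt = {"ga": [10, 10, 10, 99.0], "gb": [10, 10, 10, 99.0]}
        ko = {"ga": [10, 10, 10, 99.0],    # log2FC 0 -> unchanged
              "gb": [10, 10, 10, 199.0]}   # log2(200/100) = 1 -> excluded
        expr = _two_genotype_expr(wt, ko)
        out = select_unchanged(expr, "RelB_KO", "WT", "CpG", band=(-1.0, 1.0))
        assert out == {"ga"}

    def test_unchanged_requires_detectability(self):
        wt = {"ga": [0, 0, 0, 0]}
        expr = _two_genotype_expr(wt, wt)
        assert select_unchanged(expr, "RelB_KO", "WT", "CpG") == set()
        assert select_unchanged(expr, "RelB_KO", "WT", "CpG",
                                require_detectable=False) == {"ga"}

    def test_program_selection_container_invariants(self, small_dataset):
        sel = select_programs(small_dataset.expression)
        assert sel.hyperexpressed_genes <= sel.induced_genes
        assert not (sel.unchanged_genes & sel.hyperexpressed_genes)

    def test_planted_hyper_count_recovered_exactly(self, small_dataset):
        ds = small_dataset
        sel = select_programs(ds.expression)
        assert sel.hyperexpressed_genes == set(ds.truth.hyper_genes)
        assert sel.induced_genes == set(ds.truth.induced_genes)


class TestGeneProgramClustering:
    def test_planted_two_program_recovery(self, small_dataset):
        ds = small_dataset
        out = cluster_gene_programs(ds.expression, ds.truth.hyper_genes, k=2, seed=0)
        truth = ds.truth.gene_class.reindex(out.labels.index)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, out.labels) == 1.0
        # naming: the IFN-dependent program (collapses in IFNAR-/- at 8 h) is B
        assert set(out.labels[truth == "isg"]) == {"B"}
        assert set(out.labels[truth == "program"]) == {"A"}

    def test_k1_single_cluster(self, small_dataset):
        ds = small_dataset
        out = cluster_gene_programs(ds.expression, ds.truth.hyper_genes, k=1)
        assert out.labels.nunique() == 1


class TestProgramFoldDifferences:
    def test_identity_pair_and_known_mean(self):
        wt = {"ga": [10, 10, 10, 10], "gb": [10, 10, 10, 10]}
        ko = {"ga": [10, 10, 10, 12.2], "gb": [10, 10, 10, 18.8]}
        # at 8 h: (13.2/11, 19.8/11) = (1.2, 1.8) -> mean 1.5
        expr = _two_genotype_expr(wt, ko)
        a = ClusterAssignment(
            labels=pd.Series({"ga": "A", "gb": "A"}), k=1, seed=0, restarts=1
        )
        fd = program_fold_differences(expr, a, [("RelB_KO", "WT"), ("WT", "WT")],
                                      [0, 8])
        fd = fd.set_index(["pair", "time_h"])
        assert fd.loc[("RelB_KO/WT", 8.0), "mean_fold_difference"] \
            == pytest.approx(1.5)
        assert fd.loc[("WT/WT", 0.0), "mean_fold_difference"] == pytest.approx(1.0)
        assert fd.loc[("WT/WT", 8.0), "mean_fold_difference"] == pytest.approx(1.0)

    def test_planted_effect_recovery(self):
        """200 genes with a planted 1.4x knockout effect and log2-noise sd
        0.2 on the ratio: recovered mean within +/-0.05."""
        rng = np.random.default_rng(41)
        genes = [f"g{i}" for i in range(200)]
        base = rng.lognormal(3, 0.5, 200) + 5
        noise = 2.0 ** rng.normal(0, 0.2, 200)
        wt = {g: [b] * 4 for g, b in zip(genes, base)}
        ko = {g: [b * 1.4 * nz] * 4 for g, b, nz in zip(genes, base, noise)}
        expr = _two_genotype_expr(wt, ko)
        a = ClusterAssignment(
            labels=pd.Series("A", index=pd.Index(genes)), k=1, seed=0, restarts=1
        )
        fd = program_fold_differences(expr, a, [("RelB_KO", "WT")], [8])
        assert fd["mean_fold_difference"].iloc[0] == pytest.approx(1.4, abs=0.05)


def test_gene_order_permutation_equivariance(small_dataset):
    """Permuting gene order permutes selections identically (set equality)."""
    ds = small_dataset
    expr = ds.expression
    rng = np.random.default_rng(55)
    perm = rng.permutation(len(expr.cpm))
    from kbcomp import ExpressionMatrix

    shuffled = ExpressionMatrix(
        counts=expr.counts.iloc[perm],
        cpm=expr.cpm.iloc[perm],
        conditions=expr.conditions,
        gene_names=expr.gene_names.iloc[perm],
    )
    a, b = select_programs(expr), select_programs(shuffled)
    assert a.induced_genes == b.induced_genes
    assert a.hyperexpressed_genes == b.hyperexpressed_genes
    assert a.unchanged_genes == b.unchanged_genes
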