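import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kbcomp import (
    ValidationError,
    compute_rpkm,
    filter_min_signal,
    log2_fold_change,
    merge_master_peaks,
    select_induced_peaks,
    summarize_distribution,
)


def brute_force_merge(intervals):
    """O(n^2) pairwise merging to a fixpoint; the independent oracle."""
    items = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        out = []
        for iv in items:
            for ov in out:
                if ov[0] == iv[0] and iv[1] <= ov[2] and ov[1] <= iv[2]:
                    ov[1] = min(ov[1], iv[1])
                    ov[2] = max(ov[2], iv[2])
                    changed = True
                    break
            else:
                out.append(list(iv))
        items = out
    return sorted(tuple(iv) for iv in items)


def _df(intervals):
    return pd.DataFrame(intervals, columns=["chrom", "start", "end"])


class TestMergeMasterPeaks:
    def test_overlap_and_bookended_merge(self):
        out = merge_master_peaks([_df([("chr1", 0, 10)]), _df([("chr1", 5, 15)])])
        assert list(out.itertuples(index=False)) == [("chr1", 0, 15)]
        out = merge_master_peaks([_df([("chr1", 0, 10)]), _df([("chr1", 10, 20)])])
        assert list(out.itertuples(index=False)) == [("chr1", 0, 20)]

    def test_empty_input(self):
        assert len(merge_master_peaks([])) == 0
        assert len(merge_master_peaks([_df([])])) == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = rng.integers(1, 100)
            chroms = rng.choice(["chr1", "chr2"], n)
            starts = rng.integers(0, 500, n)
            ends = starts + rng.integers(1, 60, n)
            ivs = list(zip(chroms, starts, ends))
            got = [tuple(r) for r in merge_master_peaks([_df(ivs)])
                   .itertuples(index=False)]
            assert sorted(got) == brute_force_merge(ivs)

    def test_output_disjoint_sorted_and_coverage_bounded(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 1000, 200)
        ivs = [("chr1", s, s + w) for s, w in zip(starts, rng.integers(1, 99, 200))]
        out = merge_master_peaks([_df(ivs)])
        assert (out["start"].to_numpy()[1:] > out["end"].to_numpy()[:-1]).all()
        assert (out["end"] - out["start"]).sum() <= sum(e - s for _, s, e in ivs)


class TestComputeRpkm:
    def test_known_value_and_zero_count(self):
        counts = pd.DataFrame({"s": [100.0, 0.0]}, index=["a", "b"])
        lengths = pd.Series([1000, 500], index=["a", "b"])
        libs = pd.Series([1e7], index=["s"])
        rpkm = compute_rpkm(counts, lengths, libs)
        assert rpkm.loc["a", "s"] == pytest.approx(10.0)
        assert rpkm.loc["b", "s"] == 0.0

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 500, (20, 4)).astype(float),
                              index=[f"p{i}" for i in range(20)],
                              columns=list("wxyz"))
        lengths = pd.Series(rng.integers(100, 2000, 20), index=counts.index)
        libs = pd.Series(rng.integers(int(1e6), int(5e7), 4), index=counts.columns)
        rpkm = compute_rpkm(counts, lengths, libs)
        for i in counts.index:
            for j in counts.columns:
                expected = counts.loc[i, j] * 1e9 / (lengths[i] * libs[j])
                assert abs(rpkm.loc[i, j] - expected) < 1e-12

    def test_linearity_under_count_splitting(self):
        counts = pd.DataFrame({"s": [120.0]}, index=["a"])
        lengths = pd.Series([600], index=["a"])
        libs = pd.Series([2e6], index=["s"])
        whole = compute_rpkm(counts, lengths, libs)
        halves = compute_rpkm(counts / 2, lengths, libs)
        assert np.allclose(whole, 2 * halves)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValidationError):
            compute_rpkm(pd.DataFrame({"s": [1.0]}, index=["a"]),
                         pd.Series([100], index=["a"]),
                         pd.Series([0], index=["s"]))


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "a, b, p, expected",
        [(8, 2, 0, 2.0), (5, 5, 3, 0.0), (15, 3, 1, 2.0), (0, 0, 1, 0.0)],
    )
    def test_known_values(self, a, b, p, expected):
        assert log2_fold_change(a, b, p) == pytest.approx(expected)

    @given(
        a=st.floats(0, 1e6), b=st.floats(0, 1e6),
        p=st.floats(1e-6, 10),
    )
    def test_antisymmetry(self, a, b, p):
        assert log2_fold_change(a, b, p) == pytest.approx(
            -log2_fold_change(b, a, p), abs=1e-9
        )

    def test_zero_pseudocount_with_zero_signal_rejected(self):
        with pytest.raises(ValidationError):
            log2_fold_change(1.0, 0.0, 0.0)


class TestFilterMinSignal:
    def _table(self, values):
        from kbcomp import ConditionKey, PeakTable

        keys = [
            ConditionKey("WT", "none", 0.0, "RelA_ChIP"),
            ConditionKey("WT", "LPS", 1.0, "RelA_ChIP"),
        ]
        labels = [k.label() for k in keys]
        idx = pd.Index([f"p{i}" for i in range(len(values))], name="peak_id")
        peaks = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(len(values)) * 100,
             "end": np.arange(len(values)) * 100 + 50},
            index=idx,
        )
        signal = pd.DataFrame(values, index=idx, columns=labels)
        return PeakTable(peaks=peaks, signal=signal,
                         conditions=dict(zip(labels, keys)))

    def test_strict_threshold_boundary(self):
        # (9, 11) passes "any condition > 10"; (10, 10) fails (strict >)
        pt = self._table([[9.0, 11.0], [10.0, 10.0]])
        kept = filter_min_signal(pt, 10.0, "any_condition")
        assert list(kept.peaks.index) == ["p0"]

    def test_zero_threshold_is_identity_on_positive_table(self):
        pt = self._table([[1.0, 2.0], [3.0, 4.0]])
        assert len(filter_min_signal(pt, 0.0).peaks) == 2

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        pt = self._table(rng.uniform(0, 30, (50, 2)))
        survivors = [
            set(filter_min_signal(pt, t).peaks.index) for t in (5.0, 10.0, 20.0)
        ]
        assert survivors[2] <= survivors[1] <= survivors[0]

    def test_induced_peak_selection(self):
        pt = self._table([[5.0, 25.0], [7.0, 7.0], [2.0, 40.0]])
        unstim, stim = pt.signal.columns
        kept = select_induced_peaks(pt, stim, unstim, min_log2fc=1.0)
        # log2(26/6) = 2.12 and log2(41/3) = 3.77 pass; 0h == 1h does not
        assert list(kept.peaks.index) == ["p0", "p2"]
        assert len(select_induced_peaks(pt, stim, unstim, -np.inf).peaks) == 3


class TestSummarizeDistribution:
    def test_linear_interpolation_percentiles(self):
        s = summarize_distribution([-1.0, 0.0, 1.0])
        assert (s.n, s.mean) == (3, pytest.approx(0.0))
        assert s.p10 == pytest.approx(-0.8)
        assert s.p90 == pytest.approx(0.8)

    def test_constant_vector(self):
        s = summarize_distribution([2.5] * 7)
        assert s.mean == s.p10 == s.p90 == 2.5

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            summarize_distribution([])
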