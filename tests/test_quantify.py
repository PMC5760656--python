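import numpy as np
import pytest
from scipy import stats

import pirna_profiler as pp
from pirna_profiler.io_preprocess import SmallRNARead
from pirna_profiler.quantify import (
    MIRNA_PROXY,
    TOTAL_READS,
    NormalizationError,
    geometric_mean,
)

from conftest import make_library

ORDER = ["piRNA_clusters", "coding_RNA", "noncoding_RNA", "repeats", "intron"]


class TestComposition:
    def test_counts_and_fractions(self):
        lib = make_library(
            [("piRNA_clusters", "c1", 0)] * 8 + [("other", None, None)] * 2
        )
        df = pp.composition(lib, ORDER)
        assert df["count"].sum() == lib.total_window_reads
        by_cat = dict(zip(df["category"], df["fraction"]))
        assert by_cat["piRNA_clusters"] == pytest.approx(0.8)
        assert by_cat["other"] == pytest.approx(0.2)
        assert df["fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert list(df["category"]) == ORDER + ["other"]

    def test_single_category(self):
        lib = make_library([("intron", "i1", 3)] * 5)
        df = pp.composition(lib, ORDER)
        assert dict(zip(df["category"], df["fraction"]))["intron"] == 1.0

    def test_empty_library_errors(self):
        lib = make_library([])
        with pytest.raises(ValueError, match="no reads"):
            pp.composition(lib, ORDER)


class TestNormalization:
    def test_mirna_ratio(self):
        ref = make_library([("other", None, None)], mirna_count=200)
        alt = make_library([("other", None, None)], mirna_count=100)
        assert pp.normalization_factor(ref, alt, MIRNA_PROXY) == pytest.approx(2.0)

    def test_equal_counts_unit_factor(self):
        ref = make_library([("other", None, None)] * 3, mirna_count=50)
        alt = make_library([("other", None, None)] * 7, mirna_count=50)
        assert pp.normalization_factor(ref, alt, MIRNA_PROXY) == 1.0

    def test_zero_denominator_errors(self):
        ref = make_library([("other", None, None)], mirna_count=300)
        alt = make_library([("other", None, None)], mirna_count=0)
        with pytest.raises(NormalizationError):
            pp.normalization_factor(ref, alt, MIRNA_PROXY)

    def test_total_reads_mode(self):
        ref = make_library([("other", None, None)] * 10)
        alt = make_library([("other", None, None)] * 5)
        assert pp.normalization_factor(ref, alt, TOTAL_READS) == pytest.approx(2.0)


class TestClusterCounts:
    def _lib(self, counts, mirna=100):
        rows = []
        for cid, n in counts.items():
            rows += [("piRNA_clusters", cid, 0)] * n
        return make_library(rows, mirna_count=mirna)

    def test_scaling_and_ranks(self):
        lib = self._lib({"c1": 50, "c2": 30, "c3": 20})
        df = pp.cluster_counts(lib, ["c1", "c2", "c3"], scale=2.0)
        assert list(df["normalized_count"]) == [100.0, 60.0, 40.0]
        assert list(df["rank"]) == [1, 2, 3]

    def test_zero_cluster_listed_last(self):
        lib = self._lib({"c1": 5})
        df = pp.cluster_counts(lib, ["c1", "c2"])
        row = df[df["cluster_id"] == "c2"].iloc[0]
        assert row["raw_count"] == 0 and row["rank"] == 2

    def test_rank_invariant_to_scale(self):
        lib = self._lib({"c1": 9, "c2": 12, "c3": 1})
        r1 = list(pp.cluster_counts(lib, ["c1", "c2", "c3"], 1.0)["cluster_id"])
        r2 = list(pp.cluster_counts(lib, ["c1", "c2", "c3"], 17.3)["cluster_id"])
        assert r1 == r2

    def test_rank_recovery_from_simulation(self, desk_annotated, desk_sim):
        """Estimated cluster abundances track simulator truth (Spearman >= 0.95)."""
        reference, _, wt_lib, _ = desk_annotated
        _, wt, _ = desk_sim
        ids = reference.cluster_order
        est = pp.cluster_counts(wt_lib, ids).set_index("cluster_id")["normalized_count"]
        truth = wt.truth[wt.truth["category"] == "piRNA_clusters"]
        true_counts = truth.groupby("cluster").size().reindex(ids, fill_value=0)
        rho = stats.spearmanr(est.reindex(ids), true_counts).statistic
        assert rho >= 0.95


class TestFoldChange:
    def _pair(self, ref_counts, alt_counts, ref_mirna=100, alt_mirna=100):
        def lib(counts, mirna):
            rows = []
            for cid, n in counts.items():
                rows += [("piRNA_clusters", cid, 0)] * n
            return make_library(rows, mirna_count=mirna)

        return pp.PairedComparison(lib(ref_counts, ref_mirna), lib(alt_counts, alt_mirna))

    def test_simple_ratio(self):
        pair = self._pair({"c1": 100}, {"c1": 20})
        fc = pp.cluster_fold_change(pair, ["c1"], pseudocount=0)
        assert fc["fold_change"].iloc[0] == pytest.approx(5.0)

    def test_degenerate_zero_with_pseudocount(self):
        pair = self._pair({"c1": 1, "c2": 0}, {"c1": 1, "c2": 0})
        fc = pp.cluster_fold_change(pair, ["c1", "c2"], pseudocount=1.0)
        assert fc.set_index("cluster_id")["fold_change"]["c2"] == pytest.approx(1.0)

    def test_negative_pseudocount_rejected(self):
        pair = self._pair({"c1": 1}, {"c1": 1})
        with pytest.raises(ValueError):
            pp.cluster_fold_change(pair, ["c1"], pseudocount=-1)

    def test_direction_inversion(self):
        """With pseudocount 0 and positive counts, FC(ref/alt) * FC(alt/ref) = 1."""
        fwd = self._pair({"c1": 100, "c2": 7}, {"c1": 20, "c2": 31})
        rev = pp.PairedComparison(fwd.ref, fwd.alt, direction="alt_over_ref")
        f1 = pp.cluster_fold_change(fwd, ["c1", "c2"], 0).set_index("cluster_id")
        f2 = pp.cluster_fold_change(rev, ["c1", "c2"], 0).set_index("cluster_id")
        prod = f1["fold_change"] * f2["fold_change"]
        assert np.allclose(prod, 1.0)

    def test_scale_invariance(self):
        """Multiplying both miRNA counts by a constant leaves every FC unchanged."""
        a = self._pair({"c1": 40, "c2": 3}, {"c1": 10, "c2": 9}, 100, 50)
        b = self._pair({"c1": 40, "c2": 3}, {"c1": 10, "c2": 9}, 300, 150)
        fa = pp.cluster_fold_change(a, ["c1", "c2"], 0)["fold_change"]
        fb = pp.cluster_fold_change(b, ["c1", "c2"], 0)["fold_change"]
        assert np.allclose(fa, fb)

    def test_rows_ordered_by_ref_rank(self):
        pair = self._pair({"c1": 5, "c2": 50}, {"c1": 5, "c2": 50})
        fc = pp.cluster_fold_change(pair, ["c1", "c2"])
        assert list(fc["cluster_id"]) == ["c2", "c1"]


class TestHistogramsAndComposition:
    def test_size_distribution_counts(self):
        reads = [SmallRNARead(f"r{i}", "A" * n) for i, n in enumerate([26, 26, 30])]
        hist = pp.size_distribution(reads)
        assert hist[26] == 2 and hist[30] == 1 and hist[20] == 0

    def test_size_distribution_paired_scaling(self):
        reads = [SmallRNARead("r", "A" * 26)]
        assert pp.size_distribution(reads, scale=2.0)[26] == 2.0

    def test_first_nt_fractions(self):
        reads = [
            SmallRNARead("a", "TAAA"),
            SmallRNARead("b", "TCCC"),
            SmallRNARead("c", "GAAA"),
            SmallRNARead("d", "TTTT"),
        ]
        comp = pp.first_nt_composition(reads)
        assert comp["U"] == pytest.approx(0.75)
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_first_nt_single_read(self):
        assert pp.first_nt_composition([SmallRNARead("a", "AGG")])["A"] == 1.0

    def test_first_nt_empty_errors(self):
        with pytest.raises(ValueError):
            pp.first_nt_composition([])

    def test_geometric_mean(self):
        assert geometric_mean([1, 4]) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            geometric_mean([1.0, 0.0])
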