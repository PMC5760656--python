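import dataclasses
import warnings

import numpy as np
import pytest

import pirna_profiler as pp
from pirna_profiler.synthetic_data import (
    ClipConfig,
    GenotypeModel,
    ScenarioConfig,
    apply_genotype,
    cluster_truth_summary,
    make_reference,
    simulate_clip,
    simulate_library,
    simulate_pair,
)


def tiny_config(seed=0, **overrides):
    defaults = dict(
        seed=seed,
        n_clusters=6,
        cluster_length_range=(400, 900),
        total_cluster_reads=6_000,
        noncluster_reads={"coding_RNA": 300, "noncoding_RNA": 100,
                          "repeats": 200, "intron": 150, "other": 100},
        mirna_reads=800,
        genotype=GenotypeModel.five_prime_sparing(150, 7.0, 3),
        clip=ClipConfig(n_reads=1_500),
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


class TestReference:
    def test_deterministic_rerun(self):
        r1 = make_reference(tiny_config(7))
        r2 = make_reference(tiny_config(7))
        assert r1.clusters == r2.clusters
        assert r1.categories == r2.categories
        for c in r1.cluster_order:
            assert np.array_equal(r1.hotspot_positions[c], r2.hotspot_positions[c])

    def test_hierarchy_round_trips_through_yaml(self, tmp_path):
        ref = make_reference(tiny_config(3))
        ref.write(tmp_path)
        loaded = pp.CategoryHierarchy.from_yaml(tmp_path / "hierarchy.yaml")
        native = ref.to_hierarchy()
        assert loaded.category_names == native.category_names
        assert loaded.targets("piRNA_clusters") == native.targets("piRNA_clusters")
        assert loaded.strand_policy == native.strand_policy

    def test_abundance_is_heavy_tailed(self):
        ref = make_reference(tiny_config(1))
        w = [ref.abundance[c] for c in ref.cluster_order]
        assert w == sorted(w, reverse=True)
        assert sum(w[:3]) > 0.8  # top half dominates


class TestLibrarySimulation:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = tiny_config(9)
        _, wt1, ko1 = simulate_pair(cfg)
        _, wt2, ko2 = simulate_pair(cfg)
        for a, b, stem in ((wt1, wt2, "wt"), (ko1, ko2, "ko")):
            p1, p2 = tmp_path / f"{stem}1.fastq", tmp_path / f"{stem}2.fastq"
            a.to_fastq(p1, adapter=cfg.adapter)
            b.to_fastq(p2, adapter=cfg.adapter)
            assert p1.read_bytes() == p2.read_bytes()

    def test_truth_covers_every_read_exactly_once(self):
        lib = simulate_library(tiny_config(2))
        assert list(lib.truth["read_id"]) == [r.read_id for r in lib.reads]
        assert lib.truth["read_id"].is_unique
        for read, length in zip(lib.reads, lib.truth["length"]):
            assert len(read) == length

    def test_mirna_counts_genotype_invariant(self):
        _, wt, ko = simulate_pair(tiny_config(4))
        wt_mirna = wt.truth[wt.truth["category"] == "miRNA"]["read_id"]
        ko_mirna = ko.truth[ko.truth["category"] == "miRNA"]["read_id"]
        assert set(wt_mirna) == set(ko_mirna)

    def test_noncluster_reads_untouched_by_genotype(self):
        _, wt, ko = simulate_pair(tiny_config(4))
        for cat in ("coding_RNA", "repeats", "other"):
            assert (wt.truth["category"] == cat).sum() == (ko.truth["category"] == cat).sum()

    def test_uniform_depletion_thins_every_cluster(self):
        cfg = tiny_config(5, genotype=GenotypeModel.uniform_depletion(4.0),
                          total_cluster_reads=20_000)
        ref, wt, ko = simulate_pair(cfg)
        wt_cl = wt.truth[wt.truth["category"] == "piRNA_clusters"]
        ko_cl = ko.truth[ko.truth["category"] == "piRNA_clusters"]
        n, kept = len(wt_cl), len(ko_cl)
        se = np.sqrt(n * 0.25 * 0.75)
        assert abs(kept - n / 4) < 3 * se
        for cid, grp in wt_cl.groupby("cluster"):
            if len(grp) < 300:
                continue
            k = (ko_cl["cluster"] == cid).sum()
            se_c = np.sqrt(len(grp) * 0.25 * 0.75)
            assert abs(k - len(grp) / 4) < 4 * se_c

    def test_five_prime_sparing_thinning_arithmetic(self):
        cfg = tiny_config(6, total_cluster_reads=30_000)
        g = cfg.genotype
        ref, wt, ko = simulate_pair(cfg)
        top = set(ref.cluster_order[: g.top_k])
        wt_cl = wt.truth[(wt.truth["category"] == "piRNA_clusters")
                         & wt.truth["cluster"].isin(top)]
        ko_cl = ko.truth[(ko.truth["category"] == "piRNA_clusters")
                         & ko.truth["cluster"].isin(top)]
        # spared region: identical read sets
        wt_win = set(wt_cl[wt_cl["true_start"] < g.window_nt]["read_id"])
        ko_win = set(ko_cl[ko_cl["true_start"] < g.window_nt]["read_id"])
        assert wt_win == ko_win
        # beyond window: binomial 1/7 retention
        n_beyond = (wt_cl["true_start"] >= g.window_nt).sum()
        k_beyond = (ko_cl["true_start"] >= g.window_nt).sum()
        p = 1 / g.factor
        se = np.sqrt(n_beyond * p * (1 - p))
        assert abs(k_beyond - n_beyond * p) < 3 * se

    def test_closed_form_fc_helper(self):
        # window fraction 0 -> full factor; fraction 1 -> no change
        assert pp.expected_full_length_fc(0.0, 7.0) == pytest.approx(7.0)
        assert pp.expected_full_length_fc(1.0, 7.0) == pytest.approx(1.0)

    def test_truth_summary_window_fractions(self):
        lib = simulate_library(tiny_config(8))
        summ = cluster_truth_summary(lib.truth, 150)
        assert (summ["window_fraction"] >= 0).all() and (summ["window_fraction"] <= 1).all()
        assert summ["n_reads"].sum() == (lib.truth["category"] == "piRNA_clusters").sum()


class TestClipSimulation:
    def test_min_len_respected_and_a1_bias(self):
        cfg = tiny_config(3, clip=ClipConfig(n_reads=2_000, a1_prob=1.0))
        clip = simulate_clip(cfg)
        assert min(len(r) for r in clip.reads) >= 15
        assert all(r.seq[0] == "A" for r in clip.reads)

    def test_disabled_clip_errors(self):
        cfg = tiny_config(3, clip=ClipConfig(enabled=False))
        with pytest.raises(ValueError):
            simulate_clip(cfg)


class TestConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ValueError):
            tiny_config(0, u1_prob=1.5)

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            GenotypeModel.uniform_depletion(0.5)

    def test_top_k_exceeds_clusters(self):
        with pytest.raises(ValueError):
            tiny_config(0, genotype=GenotypeModel.five_prime_sparing(150, 7.0, 50))

    def test_infeasible_sparing_warns_not_errors(self):
        cfg = tiny_config(1, genotype=GenotypeModel.five_prime_sparing(5_000, 7.0, 3))
        with pytest.warns(UserWarning):
            simulate_pair(cfg)

    def test_yaml_round_trip(self, tmp_path):
        cfg = tiny_config(13)
        cfg.to_yaml(tmp_path / "s.yaml")
        back = ScenarioConfig.from_yaml(tmp_path / "s.yaml")
        assert back == cfg
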