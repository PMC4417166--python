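import numpy as np
import pytest

from epibind.anchors import filter_genes
from epibind.modeling import SplitSpec, pearson_cc, repeated_cv
from epibind.signal import DEFAULT_FEATURES, build_bin_feature_matrices
from epibind.synthetic import (
    SimConfig,
    ground_truth_ranks,
    latent_bin_matrices,
    simulate_annotation,
    simulate_dataset,
    simulate_feature_tracks,
    write_dataset,
)


class TestAnnotation:
    def test_decoy_count_is_exact_by_construction(self):
        cfg = SimConfig(n_genes=100, decoy_fraction=0.1)
        genes, _ = simulate_annotation(cfg, master_seed=3)
        assert len(genes) == 100
        assert len(filter_genes(genes)) == 90

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimConfig(n_genes=20, n_enhancers=3, decoy_fraction=0.1)
        for d in ("run1", "run2"):
            ds = simulate_dataset(cfg, master_seed=5, bins=[1, -1])
            write_dataset(ds, tmp_path / d)
        for name in ("genes.refflat", "enhancers.bed", "cell0/methylation.tsv",
                     "cell0/cell0_H3K4me3_rep1.bed"):
            assert (tmp_path / "run1" / name).read_bytes() == (tmp_path / "run2" / name).read_bytes()

    def test_strands_roughly_balanced(self):
        genes, _ = simulate_annotation(SimConfig(n_genes=400), master_seed=1)
        n_plus = sum(g.strand == "+" for g in genes)
        # binomial(400, 1/2): 4 sigma is 40
        assert abs(n_plus - 200) < 60

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="infeasible packing"):
            SimConfig(n_genes=100, chrom_length=50_000).resolved_chrom_length()

    def test_enhancers_distal_to_every_tss(self):
        cfg = SimConfig(n_genes=30, n_enhancers=5)
        genes, enhancers = simulate_annotation(cfg, master_seed=2)
        tsss = [g.tss for g in genes]
        for e in enhancers:
            mid = (e.start + e.end) // 2
            assert min(abs(mid - t) for t in tsss) >= 10_000

    def test_genes_do_not_overlap(self):
        genes, _ = simulate_annotation(SimConfig(n_genes=50), master_seed=9)
        spans = sorted((min(g.tss, g.tts), max(g.tss, g.tts)) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestTracks:
    def test_high_depth_rpm_tracks_latent_level(self):
        cfg = SimConfig(n_genes=150, read_depth=500.0)
        ds = simulate_dataset(cfg, master_seed=4, bins=[1])
        mats = build_bin_feature_matrices(ds.anchors, ds.feature_tracks[0],
                                          ds.methylomes[0], ds.tf_tracks[0])
        m = {x.bin_index: x for x in mats}[1]
        bi = ds.truth.bins.index(1)
        fi = DEFAULT_FEATURES.index("H3K4me3")
        r = pearson_cc(m.X[:, fi], ds.truth.ideal[0][:, fi, bi])
        assert r > 0.99

    def test_zero_depth_gives_empty_tracks(self):
        cfg = SimConfig(n_genes=20, read_depth=0.0)
        ds = simulate_dataset(cfg, master_seed=4, bins=[1])
        assert all(t.n_reads == 0 for t in ds.feature_tracks[0])

    def test_replicates_correlate_at_moderate_depth(self):
        cfg = SimConfig(n_genes=150)  # default depth ~60 reads per bin
        ds = simulate_dataset(cfg, master_seed=6, bins=[1])
        rep1, rep2 = [t for t in ds.feature_tracks[0] if t.feature_name == "H3K4me3"]
        anchors = ds.anchors
        from epibind.anchors import make_bin_windows

        v1, v2 = [], []
        for a in anchors:
            w = {x.bin_index: x for x in make_bin_windows(a.chrom, a.pos, a.strand)}[1]
            v1.append(rep1.window_profile(w.chrom, w.start, w.end).mean())
            v2.append(rep2.window_profile(w.chrom, w.start, w.end).mean())
        assert pearson_cc(v1, v2) > 0.9

    def test_bin_subset_latents_match_full_run(self):
        """Restricting simulation to a bin subset must not change the bins kept."""
        cfg = SimConfig(n_genes=60)
        sub, truth_sub = latent_bin_matrices(cfg, master_seed=8, bins=[-3, 2])
        full, truth_full = latent_bin_matrices(cfg, master_seed=8, bins=None)
        for b in (-3, 2):
            assert np.array_equal(sub[b].X, full[b].X)
            assert np.array_equal(sub[b].y, full[b].y)

    def test_tracks_depend_only_on_their_stream(self):
        cfg = SimConfig(n_genes=30)
        ds1 = simulate_dataset(cfg, master_seed=11, bins=[1])
        ds2 = simulate_dataset(cfg, master_seed=11, bins=[1])
        t1 = [t for t in ds1.feature_tracks[0] if t.feature_name == "H2az"][0]
        t2 = [t for t in ds2.feature_tracks[0] if t.feature_name == "H2az"][0]
        assert np.array_equal(t1._by_chrom[cfg.chrom][0], t2._by_chrom[cfg.chrom][0])


class TestTFTrack:
    def test_zero_weights_give_null_cv_accuracy(self):
        cfg = SimConfig(n_genes=300, weight_pattern=(0.0, 0.0, 0.0, 0.0),
                        signal_amplitude=0.0)
        mats, truth = latent_bin_matrices(cfg, master_seed=13, bins=[1])
        ev = repeated_cv(mats[1], "mlr", SplitSpec(n_repeats=5, master_seed=2))
        assert abs(ev.mean_pcc) < 0.15

    def test_read_free_bins_occur_at_low_affinity(self):
        cfg = SimConfig(n_genes=300)
        ds = simulate_dataset(cfg, master_seed=14, bins=[1])
        mats = build_bin_feature_matrices(ds.anchors, ds.feature_tracks[0],
                                          ds.methylomes[0], ds.tf_tracks[0])
        m = {x.bin_index: x for x in mats}[1]
        bi = ds.truth.bins.index(1)
        ystar = ds.truth.y_star[0][:, bi]
        missing = m.y == -1.0
        assert missing.any()
        assert ystar[missing].mean() < ystar[~missing].mean()

    def test_observed_affinity_tracks_latent(self):
        cfg = SimConfig(n_genes=200)
        ds = simulate_dataset(cfg, master_seed=15, bins=[1])
        mats = build_bin_feature_matrices(ds.anchors, ds.feature_tracks[0],
                                          ds.methylomes[0], ds.tf_tracks[0])
        m = {x.bin_index: x for x in mats}[1]
        bi = ds.truth.bins.index(1)
        assert pearson_cc(m.y, ds.truth.y_star[0][:, bi]) > 0.9


class TestMethylome:
    def test_zero_density_bin_always_missing(self):
        cfg = SimConfig(n_genes=40, cpg_base_density=0.0, cpg_peak_density=0.0)
        ds = simulate_dataset(cfg, master_seed=16, bins=[1])
        mats = build_bin_feature_matrices(ds.anchors, ds.feature_tracks[0],
                                          ds.methylomes[0], ds.tf_tracks[0])
        fi = DEFAULT_FEATURES.index("DNAmeth")
        m = {x.bin_index: x for x in mats}[1]
        assert m.missing_mask[:, fi].all()
        assert np.all(m.X[:, fi] == 0.0)

    def test_levels_always_in_unit_interval(self):
        cfg = SimConfig(n_genes=60)
        ds = simulate_dataset(cfg, master_seed=17, bins=[1, 40])
        table = ds.methylomes[0]
        _, lvl = table._by_chrom[cfg.chrom]
        assert np.all((lvl >= 0) & (lvl <= 1))


class TestGroundTruthRanks:
    def test_single_nonzero_weight_ranks_first(self):
        ranks, ties = ground_truth_ranks([0.0, 0.0, 2.5, 0.0])
        assert ranks[2] == 1 and not np.isnan(ranks).any()

    def test_equal_weights_tie_flagged(self):
        ranks, ties = ground_truth_ranks([1.0, 1.0, 1.0])
        assert ties and ranks.tolist() == [1, 2, 3]

    def test_invariant_to_global_rescaling(self):
        w = np.array([0.3, -1.2, 0.7, 0.1])
        r1, _ = ground_truth_ranks(w)
        r2, _ = ground_truth_ranks(10.0 * w)
        assert np.array_equal(r1, r2)

    def test_dataset_truth_top_features_match_pattern(self):
        cfg = SimConfig(n_genes=10)
        _, truth = latent_bin_matrices(cfg, master_seed=1, bins=[1])
        assert truth.top_features(0, truth.bins.index(1), k=2) == {"H3K4me3", "H3K9ac"}
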