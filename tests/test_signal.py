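import numpy as np
import pytest

from epibind.anchors import Anchor, BinWindow
from epibind.signal import (
    DEFAULT_FEATURES,
    MethylationTable,
    ReadSet,
    bin_mean,
    bin_methylation_level,
    build_bin_feature_matrices,
    combine_replicates,
    per_base_coverage,
    rpm,
    tf_binding_affinity,
)


def brute_force_coverage(reads, start, end):
    """Independent per-base recount by direct interval membership."""
    return np.array([sum(1 for _, s, e in reads if s <= pos < e) for pos in range(start, end)])


class TestCoverage:
    def test_overlapping_reads_counted_per_base(self):
        rs = ReadSet([("chr1", 5, 10), ("chr1", 8, 12)])
        cov = per_base_coverage(rs, BinWindow(1, "chr1", 5, 12))
        assert cov.tolist() == [1, 1, 1, 2, 2, 1, 1]

    def test_no_reads_all_zero(self):
        rs = ReadSet([])
        assert per_base_coverage(rs, BinWindow(1, "chr9", 0, 7)).tolist() == [0] * 7

    def test_spanning_read_all_ones(self):
        rs = ReadSet([("chr1", 0, 1000)])
        assert per_base_coverage(rs, BinWindow(1, "chr1", 100, 200)).tolist() == [1] * 100

    def test_matches_brute_force_on_random_read_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(0, 40))
            starts = rng.integers(0, 950, size=n)
            lengths = rng.integers(1, 120, size=n)
            reads = [("toy", int(s), int(s + l)) for s, l in zip(starts, lengths)]
            rs = ReadSet(reads)
            for b0 in range(0, 1000, 100):
                win = BinWindow(1, "toy", b0, b0 + 100)
                fast = per_base_coverage(rs, win)
                slow = brute_force_coverage(reads, b0, b0 + 100)
                assert np.array_equal(fast, slow)
                assert abs(bin_mean(fast) - slow.sum() / 100) < 1e-9


class TestScalarOps:
    def test_bin_mean_examples(self, rng):
        assert bin_mean([3] * 100) == 3.0
        assert bin_mean([0] * 50 + [1] * 50) == 0.5
        v = rng.random(100)
        assert bin_mean(v) == pytest.approx(v.sum() / 100, abs=1e-12)

    def test_bin_mean_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            bin_mean([1.0] * 99)

    def test_rpm_examples_and_linearity(self):
        assert rpm(2, 10**6) == 2.0
        assert rpm(5, 2 * 10**7) == 0.25
        assert rpm(2, 10**6) == rpm(4, 2 * 10**6)  # scale invariance
        assert rpm(3, 1234) + rpm(4, 1234) == pytest.approx(rpm(7, 1234))
        with pytest.raises(ValueError):
            rpm(1, 0)

    def test_combine_replicates(self):
        assert combine_replicates([0.4]) == 0.4
        assert combine_replicates([0.2, 0.6]) == pytest.approx(0.4)
        assert combine_replicates([1, 2, 3]) == combine_replicates([3, 1, 2])
        with pytest.raises(ValueError):
            combine_replicates([])


class TestBindingAffinity:
    def test_read_free_bin_gets_pseudo_count(self):
        assert tf_binding_affinity(0, 0.0) == -1.0

    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (3.0, 2.0)])
    def test_log2_transform(self, r, expected):
        assert tf_binding_affinity(5, r) == pytest.approx(expected)

    def test_pseudo_count_below_every_nonzero_value(self, rng):
        values = [tf_binding_affinity(1, float(r)) for r in rng.exponential(0.01, 500)]
        assert min(values) >= 0.0 > -1.0

    def test_negative_rpm_rejected(self):
        with pytest.raises(ValueError):
            tf_binding_affinity(1, -0.5)


class TestMethylation:
    def _table(self, rows):
        return MethylationTable(rows)

    def test_bin_average(self):
        t = self._table([("chr1", 10, 0.2), ("chr1", 20, 0.8)])
        assert bin_methylation_level(t, BinWindow(1, "chr1", 0, 100)) == (0.5, False)

    def test_single_cpg(self):
        t = self._table([("chr1", 55, 0.37)])
        val, missing = bin_methylation_level(t, BinWindow(1, "chr1", 0, 100))
        assert val == pytest.approx(0.37) and not missing

    def test_empty_bin_policies(self):
        t = self._table([("chr1", 500, 0.9)])
        assert bin_methylation_level(t, BinWindow(1, "chr1", 0, 100), "zero_fill") == (0.0, True)
        val, missing = bin_methylation_level(t, BinWindow(1, "chr1", 0, 100), "mask_only")
        assert np.isnan(val) and missing

    def test_out_of_range_level_rejected_at_load(self):
        with pytest.raises(ValueError):
            self._table([("chr1", 5, 1.2)])

    def test_duplicate_positions_averaged(self):
        t = self._table([("chr1", 10, 0.0), ("chr1", 10, 1.0)])
        assert bin_methylation_level(t, BinWindow(1, "chr1", 0, 100)) == (0.5, False)

    def test_from_file_three_column_and_bedgraph(self, tmp_path):
        p3 = tmp_path / "m.tsv"
        p3.write_text("chr1\t10\t0.25\n")
        p4 = tmp_path / "m.bedgraph"
        p4.write_text("chr1\t10\t12\t0.25\n")
        for p in (p3, p4):
            t = MethylationTable.from_file(p)
            assert t.levels_in("chr1", 0, 100).tolist() == [0.25]


class TestMatrixAssembly:
    def _anchor(self):
        return Anchor("a1", "chrT", 10_000, "+")

    def _tracks(self, n_per_feature=1, coverage_depth=3, library=10**6):
        tracks = []
        for fname in DEFAULT_FEATURES:
            if fname == "DNAmeth":
                continue
            for rep in range(1, n_per_feature + 1):
                reads = [("chrT", 0, 20_000)] * coverage_depth
                tracks.append(ReadSet(reads, feature_name=fname, replicate=rep,
                                      library_size=library))
        return tracks

    def test_constant_track_oracle(self):
        # uniform coverage c over the window -> every bin is exactly c * 1e6 / N
        c, N = 3, 10**6
        tracks = self._tracks(coverage_depth=c, library=N)
        tf = [ReadSet([("chrT", 0, 20_000)], feature_name="TF", library_size=N)]
        meth = MethylationTable([("chrT", i, 0.5) for i in range(6000, 14_000, 50)])
        mats = build_bin_feature_matrices([self._anchor()], tracks, meth, tf)
        assert len(mats) == 80
        for m in mats:
            hist = m.X[0, :11]
            assert np.allclose(hist, c * 1e6 / N)
            assert m.X[0, 11] == pytest.approx(0.5)

    def test_empty_tf_track_gives_pseudo_count_everywhere(self):
        tracks = self._tracks()
        tf = [ReadSet([], feature_name="TF", library_size=10**6)]
        meth = MethylationTable([])
        mats = build_bin_feature_matrices([self._anchor()], tracks, meth, tf)
        assert all(m.y[0] == -1.0 for m in mats)
        # CpG-free bins are zero-filled and flagged
        assert all(m.missing_mask[0, 11] for m in mats)

    def test_replicate_order_invariance(self, rng):
        anchor = self._anchor()
        tracks = []
        for fname in DEFAULT_FEATURES[:-1]:
            for rep in (1, 2):
                n = int(rng.integers(50, 150))
                starts = rng.integers(6000, 14_000 - 40, size=n)
                reads = [("chrT", int(s), int(s) + 36) for s in starts]
                tracks.append(ReadSet(reads, feature_name=fname, replicate=rep,
                                      library_size=50_000))
        tf = [ReadSet([("chrT", 10_050, 10_086)], feature_name="TF", library_size=1000)]
        meth = MethylationTable([("chrT", 10_010, 0.4)])
        a = build_bin_feature_matrices([anchor], tracks, meth, tf)
        b = build_bin_feature_matrices([anchor], tracks[::-1], meth, tf)
        for ma, mb in zip(a, b):
            assert np.allclose(ma.X, mb.X) and np.allclose(ma.y, mb.y)

    def test_missing_configured_feature_raises(self):
        tracks = self._tracks()[:-1]  # drop the last histone feature entirely
        tf = [ReadSet([], feature_name="TF", library_size=1)]
        with pytest.raises(ValueError, match="H4K20me1"):
            build_bin_feature_matrices([self._anchor()], tracks, MethylationTable([]), tf)

    def test_minus_strand_anchor_bins_follow_transcription(self):
        # a read downstream of a minus-strand TSS (lower coordinates) must land in +bins
        anchor = Anchor("am", "chrT", 10_000, "-")
        tracks = self._tracks()
        tf = [ReadSet([("chrT", 9_950, 9_986)], feature_name="TF", library_size=1000)]
        mats = build_bin_feature_matrices([anchor], tracks, MethylationTable([]), tf)
        by_bin = {m.bin_index: m.y[0] for m in mats}
        assert by_bin[1] > -1.0 and by_bin[-1] == -1.0
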