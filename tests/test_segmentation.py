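"""Outlier smoothing, CBS statistic/recursion, gene copy scores."""

import numpy as np
import pandas as pd
import pytest

from cnadose.formats import GeneModelSet
from cnadose.segmentation import (
    SegmentationResult,
    cbs_max_statistic,
    cbs_segment,
    gene_copy_scores,
    smooth_outliers,
)
from conftest import make_track
from oracles import brute_force_max_t


def _trimmed_sd_oracle(values, trim=0.025):
    v = np.sort(np.asarray(values, dtype=float))
    k = int(np.floor(trim * len(v)))
    core = v[k: len(v) - k] if k else v
    return core.std(ddof=1)


class TestSmoothOutliers:
    def test_constant_sequence_unchanged(self):
        track = make_track("chr1", list(range(0, 2000, 100)), [0.2] * 20)
        out = smooth_outliers(track)
        np.testing.assert_array_equal(out.probes["ratio"],
                                      track.probes["ratio"])

    def test_spike_replaced_others_untouched(self):
        rng = np.random.default_rng(8)
        ratios = rng.normal(0.0, 0.01, 41)
        ratios[20] = 5.0
        track = make_track("chr1", list(range(0, 4100, 100)), ratios)
        out = smooth_outliers(track)
        got = out.probes["ratio"].to_numpy()
        # all other probes bit-identical
        mask = np.ones(41, dtype=bool)
        mask[20] = False
        np.testing.assert_array_equal(got[mask], ratios[mask])
        # spike pulled to neighborhood median + 2 sigma (hand-derived rule)
        sigma = _trimmed_sd_oracle(ratios)
        neigh = np.delete(ratios[10:31], 10)
        expected = np.median(neigh) + 2.0 * sigma
        assert got[20] == pytest.approx(expected)

    def test_idempotent_on_spike_fixture(self):
        rng = np.random.default_rng(8)
        ratios = rng.normal(0.0, 0.01, 41)
        ratios[20] = 5.0
        track = make_track("chr1", list(range(0, 4100, 100)), ratios)
        once = smooth_outliers(track)
        twice = smooth_outliers(once)
        np.testing.assert_array_equal(once.probes["ratio"],
                                      twice.probes["ratio"])

    def test_tiny_chromosome_warns_and_passes_through(self):
        track = make_track("chr1", [0], [3.0])
        with pytest.warns(UserWarning):
            out = smooth_outliers(track)
        assert out.probes["ratio"].iloc[0] == 3.0


class TestCbsMaxStatistic:
    def test_perfect_step(self):
        i, j, t = cbs_max_statistic(np.array([0.0, 0, 0, 1, 1, 1]))
        assert {i, j} <= {0, 3, 6}
        assert (i, j) in {(0, 3), (3, 6)}
        assert j - i == 3  # the split boundary is at probe 3
        assert t == np.inf or t > 100

    def test_constant_vector_zero_statistic(self):
        i, j, t = cbs_max_statistic(np.full(10, 2.5))
        assert (i, j, t) == (0, 1, 0.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 40))
            x = rng.normal(0, 1, n)
            bi, bj, bt = brute_force_max_t(x)
            i, j, t = cbs_max_statistic(x)
            assert (i, j) == (bi, bj)
            assert t == pytest.approx(bt, rel=1e-10)

    def test_rejects_short_input(self):
        with pytest.raises(ValueError):
            cbs_max_statistic(np.array([1.0, 2.0, 3.0]))


class TestCbsSegment:
    def test_alpha_out_of_range(self, small_track):
        with pytest.raises(ValueError):
            cbs_segment(small_track, alpha=1.5)

    def test_segments_partition_probes(self, small_track):
        seg = cbs_segment(smooth_outliers(small_track), seed=1, n_perm=200)
        assert len(seg.probe_values) == len(small_track)
        for chrom, grp in seg.segments.groupby("chrom", sort=False):
            grp = grp.sort_values("start_probe")
            assert grp["start_probe"].iloc[0] == 0
            contiguous = (
                grp["start_probe"].iloc[1:].to_numpy()
                == grp["end_probe"].iloc[:-1].to_numpy() + 1
            )
            assert contiguous.all()

    def test_segment_means_are_exact_probe_means(self, small_track):
        sm = smooth_outliers(small_track)
        seg = cbs_segment(sm, seed=1, n_perm=200)
        offset = 0
        for chrom in sm.chromosomes:
            r = sm.chromosome(chrom)["ratio"].to_numpy()
            for row in seg.segments[seg.segments["chrom"] == chrom].itertuples():
                lo, hi = row.start_probe, row.end_probe + 1
                assert row.mean == r[lo:hi].mean()
                np.testing.assert_array_equal(
                    seg.probe_values[offset + lo: offset + hi], row.mean)
            offset += len(r)

    def test_planted_step_recovered(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 0.15, 100),
                               rng.normal(0.5, 0.15, 100)])
        track = make_track("chr1", list(range(0, 20000, 100)), vals)
        seg = cbs_segment(track, n_perm=500, seed=5)
        assert len(seg.segments) >= 2
        boundaries = seg.segments["start_probe"].to_numpy()[1:]
        assert np.min(np.abs(boundaries - 100)) <= 2
        # the two bulk segments are separated by roughly the planted step
        bulk = seg.segments[seg.segments["n_probes"] >= 50]
        low = bulk[bulk["end_probe"] < 100]
        high = bulk[bulk["start_probe"] >= 98]
        assert len(low) and len(high)
        assert high["mean"].min() > low["mean"].max() + 0.3

    def test_vanishing_alpha_yields_single_segments(self):
        # even a blatant step must not split when alpha is below the
        # permutation resolution
        vals = np.concatenate([np.zeros(50), np.ones(50)])
        track = make_track("chr1", list(range(0, 10000, 100)), vals)
        seg = cbs_segment(track, alpha=1e-9, n_perm=200, seed=0)
        assert len(seg.segments) == 1

    def test_deterministic_under_seed(self, small_track):
        sm = smooth_outliers(small_track)
        a = cbs_segment(sm, seed=9, n_perm=200)
        b = cbs_segment(sm, seed=9, n_perm=200)
        pd.testing.assert_frame_equal(a.segments, b.segments)
        np.testing.assert_array_equal(a.probe_values, b.probe_values)

    def test_detection_monotone_in_effect_size(self):
        # detection frequency of a planted step never decreases with effect
        detect = []
        for delta in (0.05, 0.2, 0.6):
            hits = 0
            for rep in range(10):
                rng = np.random.default_rng(1000 + rep)
                vals = np.concatenate([rng.normal(0, 0.15, 60),
                                       rng.normal(delta, 0.15, 60)])
                track = make_track("chr1", list(range(0, 12000, 100)), vals)
                seg = cbs_segment(track, n_perm=300, seed=rep)
                hits += len(seg.segments) > 1
            detect.append(hits)
        assert detect[0] <= detect[1] <= detect[2]
        assert detect[2] == 10


class TestGeneCopyScores:
    @staticmethod
    def _genes(rows):
        return GeneModelSet(pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end"]))

    def _seg_for(self, track, means_by_probe):
        segments = pd.DataFrame()  # not needed for scoring
        return SegmentationResult(segments=segments,
                                  probe_values=np.asarray(means_by_probe,
                                                          dtype=float))

    def test_gene_inside_one_segment_exact(self):
        track = make_track("chr1", [0, 100, 200, 300], [0.4, 0.4, 0.4, 0.0])
        seg = self._seg_for(track, [0.4, 0.4, 0.4, 0.0])
        genes = self._genes([("gA", "chr1", 0, 260)])
        out = gene_copy_scores(seg, track, genes)
        assert out.loc["gA", "mean_log10_ratio"] == 0.4
        assert out.loc["gA", "n_probes"] == 3

    def test_two_probe_gene_omitted(self):
        track = make_track("chr1", [0, 100, 200], [0.4, 0.4, 0.4])
        seg = self._seg_for(track, [0.4, 0.4, 0.4])
        genes = self._genes([("gA", "chr1", 0, 160)])
        assert len(gene_copy_scores(seg, track, genes)) == 0

    def test_gene_spanning_two_segments_weighted_mean(self):
        starts = [0, 100, 200, 300, 400, 500]
        track = make_track("chr1", starts, [0.0] * 6)
        m1, m2 = 0.1, 0.7
        seg = self._seg_for(track, [m1, m1, m2, m2, m2, m2])
        genes = self._genes([("gA", "chr1", 0, 560)])
        out = gene_copy_scores(seg, track, genes)
        assert out.loc["gA", "mean_log10_ratio"] == pytest.approx(
            (2 * m1 + 4 * m2) / 6)

    def test_half_open_coordinates_no_touching_overlap(self):
        # probe ending exactly at gene start does not support the gene
        track = make_track("chr1", [0, 100, 200, 300], [0.5] * 4, width=100)
        seg = self._seg_for(track, [0.5] * 4)
        genes = self._genes([("gA", "chr1", 100, 400)])
        out = gene_copy_scores(seg, track, genes)
        assert out.loc["gA", "n_probes"] == 3

    def test_gene_on_missing_chromosome_omitted(self):
        track = make_track("chr1", [0, 100, 200], [0.0] * 3)
        seg = self._seg_for(track, [0.0] * 3)
        genes = self._genes([("gA", "chrX", 0, 300)])
        assert len(gene_copy_scores(seg, track, genes)) == 0
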