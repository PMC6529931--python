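"""Interval algebra, track readers, and anchored aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromwire.genomic_io import (
    GenomicInterval,
    IntervalSet,
    ParseError,
    SignalTrack,
    aggregate_around_anchors,
    coverage_consensus,
    merge_intervals,
    nearest_distance_histogram,
    read_methylome,
)
from conftest import base_occupancy, intervalset_from_mask


def iset(*tuples):
    return IntervalSet.from_tuples(list(tuples))


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_length_and_midpoint(self):
        iv = GenomicInterval("chr1", 100, 300)
        assert iv.length == 200
        assert iv.midpoint == 200


class TestReadMethylome:
    def write(self, tmp_path, rows):
        p = tmp_path / "m.tsv"
        p.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        return p

    def test_coverage_cutoff_inclusive_at_five(self, tmp_path):
        rows = [("chr1", 100, 0.5, 4), ("chr1", 200, 0.5, 5)]
        track = read_methylome(self.write(tmp_path, rows))
        assert len(track) == 1
        assert track.df["pos"].tolist() == [200]
        assert track.df["beta"].iloc[0] == 0.5

    def test_counts_after_filtering(self, tmp_path):
        rows = [("chr1", i * 100, 0.4, 3 if i < 3 else 10) for i in range(10)]
        track = read_methylome(self.write(tmp_path, rows))
        assert len(track) == 7

    def test_malformed_line_named(self, tmp_path):
        p = self.write(tmp_path, [("chr1", 100, 0.5, 10), ("chr1", "oops", 0.5, 10)])
        with pytest.raises(ParseError, match="line 2"):
            read_methylome(p)

    def test_beta_out_of_range_rejected(self, tmp_path):
        p = self.write(tmp_path, [("chr1", 100, 1.5, 10)])
        with pytest.raises(ParseError, match="beta"):
            read_methylome(p)


class TestMergeIntervals:
    def test_overlap_merges(self):
        out = merge_intervals(iset(("chr1", 0, 10), ("chr1", 5, 20)))
        assert out.df[["start", "end"]].values.tolist() == [[0, 20]]

    def test_touching_halfopen_merge_at_zero_gap(self):
        out = merge_intervals(iset(("chr1", 0, 10), ("chr1", 10, 20)))
        assert out.df[["start", "end"]].values.tolist() == [[0, 20]]

    def test_gap_bridging(self):
        s = iset(("chr1", 0, 10), ("chr1", 15, 20))
        assert len(merge_intervals(s, min_gap=4)) == 2
        assert len(merge_intervals(s, min_gap=5)) == 1

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 200), st.integers(1, 40)),
                    min_size=1, max_size=100),
           st.integers(0, 10))
    def test_matches_base_level_union_oracle(self, raw, min_gap):
        s = iset(*[("chr1", a, a + l) for a, l in raw])
        merged = merge_intervals(s, min_gap=min_gap)
        # oracle: paint bases, bridge gaps <= min_gap by dilating runs
        cover = base_occupancy([s], 300) > 0
        if min_gap:
            from conftest import runs_from_mask
            runs = runs_from_mask(cover)
            for (a1, b1), (a2, b2) in zip(runs, runs[1:]):
                if a2 - b1 <= min_gap:
                    cover[b1:a2] = True
        expected = intervalset_from_mask(cover)
        assert merged.df[["start", "end"]].values.tolist() == \
            expected.df[["start", "end"]].values.tolist()

    def test_idempotent(self):
        s = iset(("chr1", 0, 10), ("chr1", 8, 30), ("chr2", 5, 9))
        once = merge_intervals(s)
        twice = merge_intervals(once)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestCoverageConsensus:
    def test_identical_sets(self):
        s = iset(("chr1", 0, 10), ("chr1", 50, 60))
        out = coverage_consensus([s, s, s], min_count=2)
        assert out.df[["start", "end"]].values.tolist() == [[0, 10], [50, 60]]

    def test_partial_overlap_counted_at_base_level(self):
        sets = [iset(("chr1", 0, 10)), iset(("chr1", 5, 15)), iset(("chr1", 20, 30))]
        out = coverage_consensus(sets, min_count=2)
        assert out.df[["start", "end"]].values.tolist() == [[5, 10]]

    def test_min_count_one_is_union(self):
        sets = [iset(("chr1", 0, 10)), iset(("chr1", 5, 15))]
        out = coverage_consensus(sets, min_count=1)
        assert out.df[["start", "end"]].values.tolist() == [[0, 15]]

    def test_min_count_above_n_sets_empty(self):
        assert len(coverage_consensus([iset(("chr1", 0, 10))], min_count=2)) == 0

    @pytest.mark.parametrize("min_count", [1, 2, 3])
    def test_random_inputs_match_occupancy_oracle(self, min_count):
        rng = np.random.default_rng(11)
        sets = []
        for _ in range(3):
            starts = rng.integers(0, 250, size=20)
            sets.append(iset(*[("chr1", int(a), int(a) + int(rng.integers(1, 30)))
                               for a in starts]))
        out = coverage_consensus(sets, min_count=min_count)
        expected = intervalset_from_mask(base_occupancy(sets, 300) >= min_count)
        assert out.df[["start", "end"]].values.tolist() == \
            expected.df[["start", "end"]].values.tolist()

    def test_all_sets_equals_intersection_oracle(self):
        rng = np.random.default_rng(12)
        sets = [iset(*[("chr1", int(a), int(a + rng.integers(1, 50)))
                       for a in rng.integers(0, 400, size=15)]) for _ in range(4)]
        out = coverage_consensus(sets, min_count=4)
        expected = intervalset_from_mask(base_occupancy(sets, 500) >= 4)
        assert out.df[["start", "end"]].values.tolist() == \
            expected.df[["start", "end"]].values.tolist()


def constant_track(value=3.0, length=200_000):
    t = SignalTrack()
    t.add_chrom("chr1", [0], [length], [value])
    return t


class TestAggregateAroundAnchors:
    def test_constant_track_flank_normalized_is_one(self):
        profile = aggregate_around_anchors(
            constant_track(), [("chr1", 100_000, "+")], flank=50_000, bin_size=5_000,
            normalize="flank_outside")
        assert profile.shape == (20,)
        np.testing.assert_allclose(profile, 1.0)

    def test_step_track_single_anchor(self):
        # 0.5 outside (left of 1000), 2 inside: raw profile is the step,
        # flank_outside normalization divides by the outside mean (0.5)
        t = SignalTrack()
        t.add_chrom("chr1", [0, 1000], [1000, 3000], [0.5, 2.0])
        profile = aggregate_around_anchors(t, [("chr1", 1000, "+")], flank=500, bin_size=100)
        np.testing.assert_allclose(profile, [0.5] * 5 + [2] * 5)
        normalized = aggregate_around_anchors(t, [("chr1", 1000, "+")], flank=500,
                                              bin_size=100, normalize="flank_outside")
        np.testing.assert_allclose(normalized, [1.0] * 5 + [4.0] * 5)

    def test_footprint_mode_length_contract(self):
        profile = aggregate_around_anchors(constant_track(), [("chr1", 5_000, "+")],
                                           flank=100, bin_size=1)
        assert profile.shape == (200,)

    def test_orientation_mirror_reverses_profile(self):
        rng = np.random.default_rng(7)
        length = 20_000
        vals = rng.random(20)
        t = SignalTrack()
        edges = np.linspace(0, length, 21).astype(int)
        t.add_chrom("chr1", edges[:-1], edges[1:], vals)
        mirrored = SignalTrack()
        mirrored.add_chrom("chr1", length - edges[1:][::-1], length - edges[:-1][::-1],
                           vals[::-1])
        p1 = aggregate_around_anchors(t, [("chr1", 8_000, "+")], flank=4_000, bin_size=500)
        p2 = aggregate_around_anchors(mirrored, [("chr1", length - 8_000, "-")],
                                      flank=4_000, bin_size=500)
        np.testing.assert_allclose(p1, p2)

    def test_uncovered_bins_are_missing_not_zero(self):
        t = SignalTrack()
        t.add_chrom("chr1", [1000], [2000], [5.0])
        profile = aggregate_around_anchors(t, [("chr1", 1000, "+")], flank=1000, bin_size=500)
        assert np.isnan(profile[0]) and np.isnan(profile[1])
        np.testing.assert_allclose(profile[2:], 5.0)


class TestNearestDistanceHistogram:
    def test_feature_at_anchor_hits_zero_bin(self):
        features = iset(("chr1", 90, 110))  # midpoint 100
        counts, edges, overflow = nearest_distance_histogram(features, [("chr1", 100)],
                                                             max_dist=500, bin_size=100)
        assert overflow == 0
        assert counts[np.searchsorted(edges, 0, side="right") - 1] == 1

    def test_hand_case_with_overflow(self):
        features = iset(("chr1", 95, 105))  # midpoint 100
        counts, edges, overflow = nearest_distance_histogram(
            features, [("chr1", 0), ("chr1", 1000)], max_dist=500, bin_size=100)
        assert overflow == 1  # anchor at 1000 is 900 away
        k = np.searchsorted(edges, 100, side="right") - 1
        assert counts[k] == 1 and counts.sum() == 1

    def test_empty_features_all_overflow(self):
        counts, _, overflow = nearest_distance_histogram(
            IntervalSet.empty(), [("chr1", 0), ("chr1", 10)], max_dist=500, bin_size=100)
        assert overflow == 2 and counts.sum() == 0

    def test_symmetric_features_symmetric_histogram(self):
        features = iset(("chr1", 195, 205), ("chr1", 795, 805))
        anchors = [("chr1", 300), ("chr1", 700)]  # -100 and +100... nearest each side
        counts, edges, overflow = nearest_distance_histogram(features, anchors,
                                                             max_dist=500, bin_size=100)
        assert overflow == 0
        neg = counts[: len(counts) // 2].sum()
        pos = counts[len(counts) // 2:].sum()
        assert neg == pos == 1
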