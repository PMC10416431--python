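"""Filtering, FRIP, correlation, PCA, distances, comparisons, profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import crsuspect as cs
from crsuspect.coverage import BinnedMatrix
from crsuspect.genome import intervals_frame

from conftest import brute_overlaps, random_intervals


def slist(rows):
    df = intervals_frame(rows)
    df["support"] = 7
    return cs.SuspectList(df)


def matrix_of(counts, ids=None):
    counts = np.asarray(counts)
    bins = intervals_frame([("chr1", i * 100, (i + 1) * 100) for i in range(counts.shape[1])])
    ids = ids or [f"s{i}" for i in range(counts.shape[0])]
    return BinnedMatrix(bins, counts, ids)


class TestDedup:
    def test_exact_duplicates_collapse(self):
        frags = cs.FragmentSet("s", intervals_frame([("chr1", 100, 250)] * 2))
        out, removed = cs.dedup_fragments(frags)
        assert len(out) == 1 and removed == 1

    def test_distinct_set_unchanged(self, layout_small, rng):
        df = random_intervals(rng, layout_small, 100).drop_duplicates()
        out, removed = cs.dedup_fragments(cs.FragmentSet("s", df))
        assert removed == 0 and len(out) == len(df)


class TestFilterFragments:
    def test_one_bp_overlap_removed_touching_kept(self, layout_small):
        regions = slist([("chr1", 100, 200)])
        frags = cs.FragmentSet(
            "s",
            intervals_frame([
                ("chr1", 50, 101),   # 1 bp overlap -> removed
                ("chr1", 0, 100),    # ends where region starts -> kept
                ("chr1", 200, 300),  # starts where region ends -> kept
            ]),
        )
        out = cs.filter_fragments(frags, regions, layout_small)
        assert list(out.data.itertuples(index=False, name=None)) == [
            ("chr1", 0, 100), ("chr1", 200, 300)]

    def test_partition_property(self, layout_small, rng):
        frags = cs.FragmentSet("s", random_intervals(rng, layout_small, 300))
        regions = slist(list(random_intervals(rng, layout_small, 10)
                             .itertuples(index=False, name=None)))
        kept = cs.filter_fragments(frags, regions, layout_small)
        hits = brute_overlaps(frags.data, regions.regions, layout_small)
        assert len(kept) + hits.sum() == len(frags)

    def test_matches_brute_force_survivors(self, layout_small, rng):
        frags = cs.FragmentSet("s", random_intervals(rng, layout_small, 400))
        regions = slist(list(random_intervals(rng, layout_small, 15)
                             .itertuples(index=False, name=None)))
        kept = cs.filter_fragments(frags, regions, layout_small)
        want = frags.data[~brute_overlaps(frags.data, regions.regions, layout_small)]
        pd.testing.assert_frame_equal(kept.data, want.reset_index(drop=True))


class TestSubtractPeaks:
    def test_whole_peak_removal(self, layout_small):
        regions = slist([("chr1", 1000, 2000)])
        df = intervals_frame([("chr1", 1500, 1600), ("chr1", 5000, 5100)])
        df["auc"] = [10.0, 20.0]
        df["max_height"] = [2.0, 3.0]
        out = cs.subtract_peaks(cs.PeakSet("s", df), regions, layout_small)
        assert list(out.data["start"]) == [5000]

    def test_matches_brute_force(self, layout_small, rng):
        peaks = cs.PeakSet("s", random_intervals(rng, layout_small, 100))
        regions = slist(list(random_intervals(rng, layout_small, 8)
                             .itertuples(index=False, name=None)))
        out = cs.subtract_peaks(peaks, regions, layout_small)
        want = peaks.data[~brute_overlaps(peaks.data, regions.regions, layout_small)]
        assert len(out) == len(want)


class TestFrip:
    def test_all_in_regions(self, layout_small):
        regions = slist([("chr1", 0, 1000)])
        frags = cs.FragmentSet("s", intervals_frame([("chr1", 10, 50), ("chr1", 500, 700)]))
        assert cs.frip(frags, regions, layout_small).frip == 1.0

    def test_three_of_four(self, layout_small):
        regions = slist([("chr1", 0, 100)])
        frags = cs.FragmentSet(
            "s",
            intervals_frame([
                ("chr1", 0, 50), ("chr1", 50, 99), ("chr1", 99, 150), ("chr1", 500, 600)
            ]),
        )
        summary = cs.frip(frags, regions, layout_small)
        assert summary.frip == 0.75
        assert summary.fragments_in_regions == 3

    def test_zero_after_filtering_composition(self, layout_small, rng):
        frags = cs.FragmentSet("s", random_intervals(rng, layout_small, 200))
        regions = slist(list(random_intervals(rng, layout_small, 10)
                             .itertuples(index=False, name=None)))
        filtered = cs.filter_fragments(frags, regions, layout_small)
        if len(filtered):
            assert cs.frip(filtered, regions, layout_small).frip == 0.0

    def test_empty_fragments_error(self, layout_small):
        with pytest.raises(ValueError, match="no mapped fragments"):
            cs.frip(cs.FragmentSet("s", intervals_frame()), slist([("chr1", 0, 10)]),
                    layout_small)


class TestSpearman:
    def test_identical_samples_correlate_fully(self):
        row = np.arange(50)
        corr = cs.spearman_matrix(matrix_of([row, row]))
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_rank_reversal_is_minus_one(self):
        row = np.arange(50)
        corr = cs.spearman_matrix(matrix_of([row, row[::-1]]))
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        counts = rng.integers(0, 50, (5, 200))
        corr = cs.spearman_matrix(matrix_of(counts))
        ranks = np.vstack([rankdata(r) for r in counts])
        want = np.corrcoef(ranks)
        np.testing.assert_allclose(corr.to_numpy(), want, atol=1e-12)

    def test_zero_variance_sample_flagged_nan(self, rng):
        counts = np.vstack([np.zeros(30), rng.integers(0, 9, 30), rng.integers(0, 9, 30)])
        corr = cs.spearman_matrix(matrix_of(counts))
        assert np.isnan(corr.iloc[0, 1]) and np.isnan(corr.iloc[1, 0])
        assert not np.isnan(corr.iloc[1, 2])
        assert corr.iloc[0, 0] == 1.0


class TestPCA:
    def test_two_samples_pc1_explains_everything(self, rng):
        counts = rng.integers(0, 30, (2, 100))
        result = cs.pca_scree(matrix_of(counts))
        assert result.percent_variance[0] == pytest.approx(100.0)

    def test_eigenvalue_sum_is_total_variance(self, rng):
        counts = rng.integers(0, 30, (6, 80)).astype(float)
        result = cs.pca_scree(matrix_of(counts))
        centered = counts - counts.mean(axis=0)
        total = (centered**2).sum() / (6 - 1)
        assert result.eigenvalues.sum() == pytest.approx(total)
        assert result.percent_variance.sum() == pytest.approx(100.0)

    def test_dominant_shared_bin_drives_pc1(self, layout_small, rng):
        # samples share one huge common-artifact bin; excluding it must
        # strictly reduce the PC1 share
        n = 6
        counts = rng.poisson(5.0, (n, 80)).astype(float)
        counts[:, 3] = 1000 + 100 * rng.standard_normal(n)
        m = matrix_of(counts)
        full = cs.pca_scree(m)
        excl = cs.SuspectList(intervals_frame([("chr1", 300, 400)]))
        reduced = cs.pca_scree(m, exclude=excl, layout=layout_small)
        assert reduced.n_bins_used == 79
        assert reduced.percent_variance[0] < full.percent_variance[0]

    def test_too_few_bins_errors(self):
        with pytest.raises(ValueError, match="bins"):
            cs.pca_scree(matrix_of(np.ones((3, 1))))


class TestDistanceRatio:
    def test_hand_computed_clusters(self):
        counts = np.array([[0.0, 0.0], [0.0, 2.0], [10.0, 0.0], [10.0, 2.0]])
        labels = ["a", "a", "b", "b"]
        report = cs.distance_ratio(matrix_of(counts), labels)
        assert report.intra == pytest.approx(2.0)
        # inter pairs: 10, sqrt(104), sqrt(104), 10
        assert report.inter == pytest.approx((10 + np.sqrt(104)) / 2)
        assert report.ratio == pytest.approx(report.inter / report.intra)

    def test_permutation_invariance(self, rng):
        counts = rng.random((6, 40))
        labels = ["a", "a", "b", "b", "c", "c"]
        base = cs.distance_ratio(matrix_of(counts), labels)
        perm = rng.permutation(6)
        shuffled = cs.distance_ratio(
            matrix_of(counts[perm]), [labels[i] for i in perm])
        assert shuffled.ratio == pytest.approx(base.ratio)

    def test_identical_samples_ratio_undefined(self):
        counts = np.ones((4, 10))
        with pytest.raises(ValueError, match="undefined"):
            cs.distance_ratio(matrix_of(counts), ["a", "a", "b", "b"])

    def test_no_intra_pairs_errors(self):
        counts = np.arange(20.0).reshape(2, 10)
        with pytest.raises(ValueError, match="intra"):
            cs.distance_ratio(matrix_of(counts), ["a", "b"])


class TestTwoTargetDistance:
    def test_ratio_increases_after_artifact_filtering(self):
        """Shared artifacts pull different targets together; removing them
        (fragments filtered, list bins excluded) raises inter:intra."""
        cfg = cs.SimulationConfig(seed=31)
        frag_sets, labels, truth = cs.simulate_two_target_panel(cfg)
        layout = cfg.layout
        artifact_list = cs.SuspectList(
            truth.artifact_regions[["chrom", "start", "end"]].assign(support=0))
        before = cs.bin_counts(frag_sets, layout, bin_size=10_000)
        filtered = [cs.filter_fragments(f, artifact_list, layout) for f in frag_sets]
        after = cs.exclude_bins(
            cs.bin_counts(filtered, layout, bin_size=10_000), artifact_list, layout)
        ratio_before = cs.distance_ratio(before, labels).ratio
        ratio_after = cs.distance_ratio(after, labels).ratio
        assert ratio_after > ratio_before


class TestListStats:
    def test_genome_fraction(self, layout_small):
        assert cs.genome_fraction(slist([]), layout_small) == 0.0
        one_kb = slist([("chr1", 0, 1000)])
        assert cs.genome_fraction(one_kb, layout_small) == pytest.approx(1000 / 20_000)

    def test_identical_lists_fully_shared(self, layout_small):
        a = slist([("chr1", 0, 100), ("chr2", 50, 80)])
        cmpres = cs.compare_lists(a, a, layout_small)
        assert cmpres.unique_a == cmpres.unique_b == 0
        assert cmpres.shared_a == cmpres.shared_b == 2
        assert cmpres.bp_shared == cmpres.bp_a == 130

    def test_disjoint_lists(self, layout_small):
        a = slist([("chr1", 0, 100)])
        b = slist([("chr2", 0, 100)])
        cmpres = cs.compare_lists(a, b, layout_small)
        assert cmpres.shared_a == cmpres.shared_b == 0 and cmpres.bp_shared == 0

    def test_random_lists_match_brute_force(self, layout_small, rng):
        fa = random_intervals(rng, layout_small, 40)
        fb = random_intervals(rng, layout_small, 40)
        cmpres = cs.compare_lists(cs.SuspectList(fa), cs.SuspectList(fb), layout_small)
        a_hits = brute_overlaps(fa, fb, layout_small)
        b_hits = brute_overlaps(fb, fa, layout_small)
        assert cmpres.shared_a == a_hits.sum() and cmpres.unique_a == (~a_hits).sum()
        assert cmpres.shared_b == b_hits.sum() and cmpres.unique_b == (~b_hits).sum()


class TestAverageProfile:
    def test_constant_track_flat_profile(self, layout_small):
        frags = cs.FragmentSet("s", intervals_frame([("chr1", 0, 10_000)] * 3))
        track = cs.fragments_to_coverage(frags, layout_small)
        result = cs.average_profile(track, slist([("chr1", 2000, 4000)]), nbins=20)
        np.testing.assert_allclose(result.profile, 3.0)

    def test_single_region_matches_direct_binning(self, layout_small, rng):
        df = random_intervals(rng, layout_small, 100, chroms=("chr1",))
        track = cs.fragments_to_coverage(cs.FragmentSet("s", df), layout_small)
        region = ("chr1", 1000, 2000)
        result = cs.average_profile(track, slist([region]), nbins=10)
        dense = np.zeros(10_000)
        for rec in df.itertuples(index=False):
            dense[rec.start:rec.end] += 1
        want = dense[1000:2000].reshape(10, 100).mean(axis=1)
        np.testing.assert_allclose(result.profile, want)

    def test_linear_in_coverage(self, layout_small, rng):
        df = random_intervals(rng, layout_small, 50, chroms=("chr1",))
        track = cs.fragments_to_coverage(cs.FragmentSet("s", df), layout_small)
        doubled = track.scaled(2.0)
        regions = slist([("chr1", 100, 900), ("chr1", 3000, 3700)])
        one = cs.average_profile(track, regions, flank=50, nbins=12)
        two = cs.average_profile(doubled, regions, flank=50, nbins=12)
        np.testing.assert_allclose(two.profile, 2 * one.profile)

    def test_truncation_flagged(self, layout_small):
        track = cs.CoverageTrack.zeros(layout_small)
        result = cs.average_profile(track, slist([("chr1", 0, 100)]), flank=500, nbins=5)
        assert result.n_truncated == 1


class TestMappability:
    def _track(self, layout, runs):
        steps = {}
        for chrom, bounds, values in runs:
            steps[chrom] = (np.array(bounds), np.array(values, dtype=float))
        return cs.CoverageTrack.from_steps(layout, steps)

    def test_extremes(self, layout_small):
        regions = slist([("chr1", 0, 100), ("chr2", 0, 100)])
        mapp = self._track(
            layout_small,
            [("chr1", [0, 10_000], [0.0]), ("chr2", [0, 8_000], [1.0])],
        )
        out = cs.flag_low_mappability(regions, mapp)
        assert list(out.regions["low_mappability"]) == [True, False]

    def test_mixed_region_mean(self, layout_small):
        mapp = self._track(layout_small, [("chr1", [0, 50, 100, 10_000], [1.0, 0.2, 1.0])])
        out = cs.flag_low_mappability(slist([("chr1", 0, 100)]), mapp, cutoff=0.7)
        assert out.regions["mean_mappability"].iloc[0] == pytest.approx(0.6)
        assert bool(out.regions["low_mappability"].iloc[0])

    def test_rejects_out_of_range_values(self, layout_small):
        mapp = self._track(layout_small, [("chr1", [0, 10_000], [2.0])])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cs.flag_low_mappability(slist([("chr1", 0, 10)]), mapp)
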