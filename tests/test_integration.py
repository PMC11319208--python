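"""Compartment multi-omic statistics, enhancers and CN classification."""

import numpy as np
import pytest
from scipy import stats

from hictopo.compartments import CompartmentTrack
from hictopo.genome import GenomeBins
from hictopo.integration import (
    CopyNumberProfile,
    ExpressionTable,
    call_candidate_enhancers,
    classify_copy_number,
    compartment_overlap_stats,
    consensus_peaks,
    enhancer_contact_sum,
    enhancer_expression_tstat,
    overlap_battery,
)
from hictopo.intervals import (
    IntervalTrack,
    bases_per_bin,
    coverage_regions,
    merge_intervals,
    overlaps_any,
)

from conftest import matrix_from_dense, symmetric_random

BINS = GenomeBins({"chr1": 1_000_000}, 10_000)  # 100 bins


def track_of(labels):
    labels = np.asarray(labels, dtype="<U2")
    return CompartmentTrack({"chr1": labels},
                            {"chr1": np.where(labels == "A", 1.0, -1.0)})


def half_ab():
    return track_of(["A"] * 50 + ["B"] * 50)


class TestIntervalOps:
    def test_merge_against_naive(self, rng):
        ivs = np.sort(rng.integers(0, 1000, size=(200, 2)), axis=1)
        ivs = ivs[ivs[:, 1] > ivs[:, 0]]
        merged = merge_intervals(ivs)
        covered = np.zeros(1001, dtype=bool)
        for s, e in ivs:
            covered[s:e] = True
        naive = covered.sum()
        assert (merged[:, 1] - merged[:, 0]).sum() == naive
        assert (merged[1:, 0] > merged[:-1, 1]).all()

    def test_coverage_regions_against_naive(self, rng):
        tracks = []
        for _ in range(5):
            ivs = np.sort(rng.integers(0, 500, size=(20, 2)), axis=1)
            tracks.append(ivs[ivs[:, 1] > ivs[:, 0]])
        for k in (2, 3):
            out = coverage_regions(tracks, k)
            depth = np.zeros(501, dtype=int)
            for t in tracks:
                cov = np.zeros(501, dtype=bool)
                for s, e in t:
                    cov[s:e] = True
                depth += cov
            naive = depth[:-1] >= k
            got = np.zeros(500, dtype=bool)
            for s, e in out:
                got[s:e] = True
            np.testing.assert_array_equal(got, naive)

    def test_overlaps_any_against_naive(self, rng):
        q = np.sort(rng.integers(0, 300, size=(50, 2)), axis=1)
        q = q[q[:, 1] > q[:, 0]]
        t = np.sort(rng.integers(0, 300, size=(30, 2)), axis=1)
        t = t[t[:, 1] > t[:, 0]]
        got = overlaps_any(q, t)
        naive = np.array([any(s < te and e > ts for ts, te in t)
                          for s, e in q])
        np.testing.assert_array_equal(got, naive)

    def test_bases_per_bin_sums_to_merged_total(self, rng):
        ivs = np.sort(rng.integers(0, 100_000, size=(40, 2)), axis=1)
        ivs = ivs[ivs[:, 1] > ivs[:, 0]]
        cov = bases_per_bin(ivs, 10, 10_000)
        assert cov.sum() == (merge_intervals(ivs)[:, 1]
                             - merge_intervals(ivs)[:, 0]).sum()


class TestCompartmentOverlap:
    def test_feature_covering_everything_gives_fraction_one(self):
        tracks = {"S1": half_ab(), "S2": half_ab()}
        feat = IntervalTrack({"chr1": np.array([[0, 1_000_000]])})
        res = compartment_overlap_stats(tracks, {"S1": feat, "S2": feat},
                                        BINS, "fraction")
        np.testing.assert_allclose(res["A"], 1.0)
        np.testing.assert_allclose(res["B"], 1.0)

    def test_mutations_only_in_b_give_zero_a_rate(self):
        tracks = {"S1": half_ab()}
        muts = IntervalTrack({"chr1": np.array([[700_000, 700_001],
                                                [900_000, 900_001]])})
        res = compartment_overlap_stats(tracks, {"S1": muts}, BINS, "per_mb")
        assert res["A"][0] == 0.0
        assert res["B"][0] == pytest.approx(2 / 0.5)

    def test_mean_tpm_uses_tss_bin_label(self):
        tracks = {"S1": half_ab()}
        expr = ExpressionTable(["g1", "g2", "g3"], np.array(["chr1"] * 3),
                               np.array([10_000, 20_000, 800_000]),
                               np.array([9.0, 3.0, 100.0]))
        res = compartment_overlap_stats(tracks, {"S1": expr}, BINS, "mean_tpm")
        assert res["A"][0] == pytest.approx(6.0)
        assert res["B"][0] == pytest.approx(100.0)

    def test_sample_in_one_input_dropped(self):
        tracks = {"S1": half_ab(), "S2": half_ab()}
        feat = {"S1": IntervalTrack({"chr1": np.array([[0, 500_000]])})}
        res = compartment_overlap_stats(tracks, feat, BINS, "fraction")
        assert res["samples"] == ["S1"]

    def test_fraction_values_in_unit_interval_and_na_excluded(self, rng):
        labels = rng.choice(["A", "B", "NA"], size=100)
        # ensure both compartments exist
        labels[:3] = "A"
        labels[3:6] = "B"
        tracks = {"S1": track_of(labels)}
        ivs = np.sort(rng.integers(0, 1_000_000, size=(30, 2)), axis=1)
        ivs = ivs[ivs[:, 1] > ivs[:, 0]]
        feat = {"S1": IntervalTrack({"chr1": ivs})}
        res = compartment_overlap_stats(tracks, feat, BINS, "fraction")
        assert 0.0 <= res["A"][0] <= 1.0
        assert 0.0 <= res["B"][0] <= 1.0

    def test_battery_applies_bh_across_features(self):
        tracks = {f"S{i}": half_ab() for i in range(8)}
        rng = np.random.default_rng(0)
        feats = {}
        for name, lo, hi in [("f1", 0, 500_000), ("f2", 500_000, 1_000_000)]:
            per = {s: IntervalTrack({"chr1": np.array([[lo, hi]])}) for s in tracks}
            feats[name] = (per, "fraction")
        df = overlap_battery(tracks, feats, BINS)
        assert set(df.columns) >= {"feature", "pvalue", "p_adj", "significant"}
        assert (df["p_adj"] >= df["pvalue"] - 1e-15).all()


class TestConsensusAndEnhancers:
    def test_identical_peak_in_two_samples_kept(self):
        t = IntervalTrack({"chr1": np.array([[100, 200]])})
        out = consensus_peaks([t, t], min_samples=2)
        np.testing.assert_array_equal(out.intervals["chr1"], [[100, 200]])

    def test_peak_in_one_of_five_dropped(self):
        t1 = IntervalTrack({"chr1": np.array([[100, 200]])})
        empty = IntervalTrack({"chr1": np.zeros((0, 2), dtype=np.int64)})
        out = consensus_peaks([t1] + [empty] * 4, min_samples=2)
        assert out.intervals.get("chr1", np.zeros((0, 2))).size == 0

    def test_consensus_monotone_in_min_samples(self, rng):
        tracks = []
        for _ in range(5):
            ivs = np.sort(rng.integers(0, 10_000, size=(15, 2)), axis=1)
            tracks.append(IntervalTrack({"chr1": ivs[ivs[:, 1] > ivs[:, 0]]}))
        prev = None
        for k in (2, 3, 4):
            tot = consensus_peaks(tracks, k).total_bases()
            if prev is not None:
                assert tot <= prev
            prev = tot

    def test_enhancer_threshold_boundary_inclusive(self):
        peaks = IntervalTrack({"chr1": np.array([[100, 200], [300, 400]])})
        hmr_hit = IntervalTrack({"chr1": np.array([[150, 160]])})
        hmr_miss = IntervalTrack({"chr1": np.zeros((0, 2), dtype=np.int64)})
        # peak 1 hypomethylated in 2/20 samples (10%, kept); peak 2 in 1/20 (5%)
        by_sample = [hmr_hit, hmr_hit] + [hmr_miss] * 18
        by_sample[2] = IntervalTrack({"chr1": np.array([[350, 360]])})
        out = call_candidate_enhancers(peaks, by_sample, threshold=0.10)
        np.testing.assert_array_equal(out.intervals["chr1"], [[100, 200]])
        assert out.scores["chr1"][0] == pytest.approx(0.10)

    def test_zero_samples_rejected(self):
        peaks = IntervalTrack({"chr1": np.array([[0, 10]])})
        with pytest.raises(ValueError):
            call_candidate_enhancers(peaks, [])


class TestEnhancerContact:
    def test_single_enhancer_bin_returns_matrix_column(self, rng):
        dense = symmetric_random(30, rng)
        m = matrix_from_dense(dense)
        enh = IntervalTrack({"chr1": np.array([[50_000, 60_000]])})
        out = enhancer_contact_sum(m, enh)["chr1"]
        np.testing.assert_allclose(out, dense[:, 5])

    def test_chromosome_without_enhancers_gives_zeros(self, rng):
        m = matrix_from_dense(symmetric_random(30, rng))
        out = enhancer_contact_sum(m, IntervalTrack({}))["chr1"]
        assert not out.any()

    def test_matches_direct_summation(self, rng):
        dense = symmetric_random(40, rng)
        m = matrix_from_dense(dense)
        enh = IntervalTrack({"chr1": np.array([[0, 30_000], [200_000, 220_000]])})
        out = enhancer_contact_sum(m, enh)["chr1"]
        cols = [0, 1, 2, 20, 21]
        np.testing.assert_allclose(out, dense[:, cols].sum(axis=1))


class TestTstat:
    def make_expr(self, values):
        return {
            f"S{i}": ExpressionTable(["g"], np.array(["chr1"]),
                                     np.array([100]), np.array([v]), f"S{i}")
            for i, v in enumerate(values)
        }

    def test_equal_group_means_give_zero(self):
        expr = self.make_expr([4.0, 6.0, 4.0, 6.0])
        t, p = enhancer_expression_tstat(expr, {"S0", "S1"}, "g")
        assert t == pytest.approx(0.0)

    def test_matches_direct_welch_computation(self, rng):
        vals = rng.lognormal(2, 0.5, size=20)
        vals[:10] *= 2
        expr = self.make_expr(vals)
        hypo = {f"S{i}" for i in range(10)}
        t, p = enhancer_expression_tstat(expr, hypo, "g")
        ref = stats.ttest_ind(vals[:10], vals[10:], equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        assert t > 0  # hypomethylated group planted higher

    def test_small_group_flagged(self):
        expr = self.make_expr([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            enhancer_expression_tstat(expr, {"S0"}, "g")


class TestCopyNumber:
    def profile(self, mn, mx, chrom_type="autosomal", ploidy=2.0):
        return CopyNumberProfile(["g"], np.array([mn]), np.array([mx]),
                                 [chrom_type], ploidy)

    @pytest.mark.parametrize("mn,mx,ct,expected", [
        (4.0, 4.5, "autosomal", "amplified"),      # 4.0 > 2.0 x 1.95
        (3.9, 4.0, "autosomal", "neutral"),        # 3.9 == cutoff, not above
        (1.85, 2.0, "sex", "amplified"),           # 1.85 > 2.0 x 0.9
        (1.0, 1.5, "autosomal", "deleted"),        # min < 1.1
        (0.7, 1.0, "sex", "deleted"),              # min < 0.75
        (0.3, 0.4, "autosomal", "biallelic_loss"),  # max < 0.5
        (0.3, 0.4, "sex", "biallelic_loss"),
        (2.0, 2.2, "autosomal", "neutral"),
        (1.0, 1.8, "sex", "neutral"),
    ])
    def test_threshold_rules(self, mn, mx, ct, expected):
        assert classify_copy_number(self.profile(mn, mx, ct), "g") == expected

    def test_biallelic_precedence_over_deleted(self):
        assert classify_copy_number(self.profile(0.1, 0.4), "g") == "biallelic_loss"

    def test_negative_cn_rejected(self):
        with pytest.raises(ValueError):
            CopyNumberProfile(["g"], np.array([-1.0]), np.array([1.0]),
                              ["autosomal"], 2.0)
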