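"""SV filtering, size-matched background, breakpoint signatures and the
same-TAD enrichment test."""

import numpy as np
import pytest
from scipy import stats

from hictopo.genome import GenomeBins
from hictopo.svtopo import (
    SVRecord,
    breakpoint_signature,
    differential_contact_map,
    filter_svs,
    read_bedpe,
    same_tad_fraction,
    size_matched_background,
    sv_tad_enrichment_test,
    write_bedpe,
)
from hictopo.tads import TadSet

from conftest import matrix_from_dense, symmetric_random


def sv(sv_type="deletion", chrom="chr1", bp1=1_000_000, bp2=2_000_000,
       pe=20, sp=20, germ=0, **kw):
    return SVRecord(sv_type, chrom, bp1, bp2, pe, sp, germ, **kw)


class TestFilterSvs:
    @pytest.mark.parametrize("record,kept", [
        (sv(bp1=0, bp2=50_000_000, pe=10, sp=10, germ=0), True),   # 50 Mb, 10/10/0
        (sv(bp1=0, bp2=50_000_001), False),                        # > 50 Mb
        (sv(sp=9), False),                                         # spanning < 10
        (sv(pe=9), False),                                         # PE < 10
        (sv(germ=1), False),                                       # germline support
        (sv(sv_type="translocation"), False),                      # wrong type
        (sv(), True),
    ])
    def test_threshold_rules(self, record, kept):
        assert (filter_svs([record]) == [record]) is kept


class TestBackground:
    bins = GenomeBins({"chr1": 10_000_000, "chr2": 6_000_000}, 10_000)
    gaps = {"chr1": [(3_000_000, 3_300_000)], "chr2": [(1_000_000, 1_200_000)]}

    def test_counts_sizes_and_types_preserved(self, rng):
        svs = [sv("deletion", bp1=0, bp2=500_000),
               sv("inversion", bp1=100_000, bp2=2_100_000),
               sv("duplication", bp1=50_000, bp2=123_456)]
        bg = size_matched_background(svs, self.bins, self.gaps, k=10, seed=3)
        assert len(bg) == 30
        assert all(b.is_background for b in bg)
        assert sorted(b.size for b in bg) == sorted(s.size for s in svs for _ in range(10))
        assert {b.sv_type for b in bg} == {s.sv_type for s in svs}

    def test_no_gap_overlap_in_thousand_placements(self, rng):
        svs = [sv(bp1=0, bp2=400_000)] * 100
        bg = size_matched_background(svs, self.bins, self.gaps, k=10, seed=9)
        assert len(bg) == 1000
        for b in bg:  # brute-force interval intersection
            for gs, ge in self.gaps.get(b.chrom, []):
                assert not (b.bp1 < ge and b.bp2 > gs)
            assert b.bp2 <= self.bins.lengths[b.chrom]

    def test_deterministic_given_seed(self):
        svs = [sv(bp1=0, bp2=800_000)]
        a = size_matched_background(svs, self.bins, self.gaps, k=10, seed=7)
        b = size_matched_background(svs, self.bins, self.gaps, k=10, seed=7)
        assert [(x.chrom, x.bp1, x.bp2) for x in a] == \
               [(x.chrom, x.bp1, x.bp2) for x in b]

    def test_fully_gapped_chromosome_excluded(self):
        gaps = {"chr2": [(0, 6_000_000)]}
        svs = [sv(bp1=0, bp2=500_000)] * 20
        bg = size_matched_background(svs, self.bins, gaps, k=10, seed=1)
        assert all(b.chrom == "chr1" for b in bg)

    def test_impossible_placement_raises(self):
        tiny = GenomeBins({"chr1": 1_000_000}, 10_000)
        with pytest.raises(ValueError):
            size_matched_background([sv(bp1=0, bp2=2_000_000)], tiny, {}, seed=1)


class TestBedpeIO:
    def test_roundtrip(self, tmp_path):
        svs = [sv(sample_id="S1"), sv("inversion", bp1=5, bp2=99, sample_id="S2")]
        write_bedpe(svs, tmp_path / "x.bedpe")
        back = read_bedpe(tmp_path / "x.bedpe")
        assert back == svs


class TestBreakpointSignature:
    def test_single_sv_signature_is_its_own_submatrix(self, rng):
        dense = symmetric_random(200, rng)
        m = matrix_from_dense(dense)
        rec = sv(bp1=500_000, bp2=1_500_000)  # bins 50 and 150
        sig = breakpoint_signature([(m, [rec])], span_bp=600_000)["deletion"]
        assert sig.n_svs == 1
        f = sig.flank_bins
        np.testing.assert_array_equal(
            sig.matrix, dense[np.ix_(range(50 - f, 50 + f + 1),
                                     range(150 - f, 150 + f + 1))])

    def test_zero_matrices_give_zero_signature(self):
        m = matrix_from_dense(np.zeros((200, 200)))
        sig = breakpoint_signature([(m, [sv(bp1=500_000, bp2=1_500_000)])])
        assert not sig["deletion"].matrix.any()

    def test_translation_equivariance(self, rng):
        dense = symmetric_random(120, rng)
        shift = 7
        shifted = np.roll(np.roll(dense, shift, axis=0), shift, axis=1)
        rec = sv(bp1=400_000, bp2=700_000)
        rec2 = sv(bp1=400_000 + shift * 10_000, bp2=700_000 + shift * 10_000)
        s1 = breakpoint_signature([(matrix_from_dense(dense), [rec])])["deletion"]
        s2 = breakpoint_signature([(matrix_from_dense(shifted), [rec2])])["deletion"]
        np.testing.assert_allclose(s1.matrix, s2.matrix)

    def test_breakpoint_near_chromosome_end_partial_occupancy(self, rng):
        dense = symmetric_random(80, rng)
        m = matrix_from_dense(dense)
        rec = sv(bp1=10_000, bp2=600_000)
        sig = breakpoint_signature([(m, [rec])])["deletion"]
        assert sig.matrix.shape == (61, 61)  # F = 30 bins at 10 kb


class TestSameTadFraction:
    bins = GenomeBins({"chr1": 2_000_000}, 10_000)

    def test_single_genome_wide_domain(self):
        t = TadSet(self.bins, [("chr1", 0, 200)])
        assert same_tad_fraction([sv(bp1=10_000, bp2=1_900_000)], t) == 1.0

    def test_adjacent_domains_give_zero(self):
        t = TadSet(self.bins, [("chr1", 0, 100), ("chr1", 100, 200)])
        svs = [sv(bp1=500_000, bp2=1_500_000)]
        assert same_tad_fraction(svs, t) == 0.0

    def test_matches_direct_interval_lookup(self, rng):
        cuts = [0, 40, 90, 140, 200]
        t = TadSet(self.bins, [("chr1", a, b) for a, b in zip(cuts, cuts[1:])])
        svs = []
        for _ in range(50):
            b1, b2 = sorted(rng.integers(0, 1_999_999, size=2))
            if b2 > b1:
                svs.append(sv(bp1=int(b1), bp2=int(b2)))
        frac = same_tad_fraction(svs, t)
        direct = np.mean([
            any(a <= s.bp1 // 10_000 < b and a <= s.bp2 // 10_000 < b
                for a, b in zip(cuts, cuts[1:]))
            for s in svs])
        assert frac == pytest.approx(direct)


class TestEnrichmentTest:
    bins = GenomeBins({"chr1": 2_000_000}, 10_000)

    def make_tads(self, n):
        return {f"S{i}": TadSet(self.bins, [("chr1", 0, 100), ("chr1", 100, 200)])
                for i in range(n)}

    def test_identical_real_and_background_give_p_one(self):
        tads = self.make_tads(6)
        svs = {s: [sv(bp1=100_000, bp2=200_000)] for s in tads}
        res = sv_tad_enrichment_test(svs, svs, tads)
        assert res["deletion"]["pvalue"] == 1.0

    def test_label_swap_symmetry(self, rng):
        tads = self.make_tads(8)
        real, bg = {}, {}
        for s in tads:
            real[s] = [sv(bp1=int(a), bp2=int(a) + 300_000)
                       for a in rng.integers(0, 1_500_000, size=5)]
            bg[s] = [sv(bp1=int(a), bp2=int(a) + 300_000)
                     for a in rng.integers(0, 1_500_000, size=5)]
        r1 = sv_tad_enrichment_test(real, bg, tads)
        r2 = sv_tad_enrichment_test(bg, real, tads)
        assert r1["deletion"]["pvalue"] == pytest.approx(r2["deletion"]["pvalue"])
        assert r1["deletion"]["median_difference"] == pytest.approx(
            -r2["deletion"]["median_difference"])

    def test_samples_without_type_dropped(self):
        tads = self.make_tads(4)
        real = {s: [sv(bp1=100_000, bp2=200_000)] for s in tads}
        real["S0"] = []  # no deletions in S0
        bg = {s: [sv(bp1=100_000, bp2=1_500_000)] for s in tads}
        res = sv_tad_enrichment_test(real, bg, tads)
        assert "S0" not in res["deletion"]["samples"]

    def test_fewer_than_two_samples_rejected(self):
        tads = self.make_tads(1)
        with pytest.raises(ValueError):
            sv_tad_enrichment_test({}, {}, tads)


class TestDifferentialContactMap:
    def test_case_equals_control_gives_zeros(self, rng):
        dense = symmetric_random(50, rng)
        m = matrix_from_dense(dense)
        out = differential_contact_map([m], [m], "chr1", (0, 500_000))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_output_median_is_zero(self, rng):
        a = matrix_from_dense(symmetric_random(50, rng))
        b = matrix_from_dense(symmetric_random(50, rng))
        out = differential_contact_map([a], [b], "chr1", (0, 500_000))
        assert np.median(out) == pytest.approx(0.0, abs=1e-12)

    def test_planted_enrichment_block_stands_out(self, rng):
        base = symmetric_random(60, rng, low=1.0, high=1.2)
        enriched = base.copy()
        enriched[10:20, 10:20] *= 2.0
        out = differential_contact_map(
            [matrix_from_dense(enriched)], [matrix_from_dense(base)],
            "chr1", (0, 600_000), eps=1e-6)
        inside = out[10:20, 10:20].mean()
        outside_mask = np.ones_like(out, dtype=bool)
        outside_mask[10:20, 10:20] = False
        assert inside - out[outside_mask].mean() == pytest.approx(1.0, abs=0.1)
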