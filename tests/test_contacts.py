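"""Contact-matrix I/O, ICE balancing, distance decay and the noise filter."""

import numpy as np
import pytest

from hictopo.contacts import (
    expected_by_distance,
    filter_low_contacts,
    ice_normalize,
    observed_over_expected,
    read_contacts,
    write_contacts,
)
from hictopo.genome import GenomeBins

from conftest import matrix_from_dense, symmetric_random


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestTripletIO:
    def test_empty_triplet_gives_zero_matrix(self, tmp_path):
        m = matrix_from_dense(np.zeros((6, 6)))
        write_contacts(m, tmp_path / "t.tsv", tmp_path / "b.bed")
        back = read_contacts(tmp_path / "t.tsv", tmp_path / "b.bed")
        assert back.mats["chr1"].sum() == 0

    def test_single_row_sets_symmetric_entries(self, tmp_path):
        (tmp_path / "b.bed").write_text(
            "".join(f"chr1\t{i*10000}\t{(i+1)*10000}\t{i}\n" for i in range(8)))
        (tmp_path / "t.tsv").write_text("3\t5\t2.0\n")
        m = read_contacts(tmp_path / "t.tsv", tmp_path / "b.bed")
        assert m.mats["chr1"][3, 5] == 2.0
        assert m.mats["chr1"][5, 3] == 2.0

    def test_roundtrip_random_matrix_is_exact(self, tmp_path, rng):
        dense = np.zeros((20, 20))
        idx = rng.integers(0, 20, size=(100, 2))
        vals = rng.uniform(0.01, 9.0, size=100)
        for (i, j), v in zip(idx, vals):
            dense[i, j] = dense[j, i] = v
        m = matrix_from_dense(dense)
        write_contacts(m, tmp_path / "t.tsv", tmp_path / "b.bed")
        back = read_contacts(tmp_path / "t.tsv", tmp_path / "b.bed")
        np.testing.assert_array_equal(back.mats["chr1"], dense)
        # and the re-written files are byte-identical
        write_contacts(back, tmp_path / "t2.tsv", tmp_path / "b2.bed")
        assert (tmp_path / "t.tsv").read_bytes() == (tmp_path / "t2.tsv").read_bytes()

    @pytest.mark.parametrize("row,err", [
        ("99\t1\t2.0\n", "outside bins table"),
        ("1\t2\t-0.5\n", "negative"),
    ])
    def test_bad_rows_rejected_with_line(self, tmp_path, row, err):
        (tmp_path / "b.bed").write_text(
            "".join(f"chr1\t{i*10000}\t{(i+1)*10000}\t{i}\n" for i in range(8)))
        (tmp_path / "t.tsv").write_text(row)
        with pytest.raises(ValueError, match=err):
            read_contacts(tmp_path / "t.tsv", tmp_path / "b.bed")


# ---------------------------------------------------------------------------
# ICE
# ---------------------------------------------------------------------------

def sinkhorn_oracle(mat: np.ndarray, iters: int = 5000) -> np.ndarray:
    """Independent fixed-point balancing: alternately normalize rows and
    columns to the mean marginal, run to tight convergence, rescale to the
    input total."""
    w = mat.astype(float).copy()
    for _ in range(iters):
        r = w.sum(axis=1)
        w = w / (r / r.mean())[:, None]
        c = w.sum(axis=0)
        w = w / (c / c.mean())[None, :]
    return w * (mat.sum() / w.sum())


class TestIce:
    def test_constant_matrix_is_fixed_point(self):
        m = matrix_from_dense(np.full((10, 10), 3.0))
        out = ice_normalize(m, tol=1e-8)
        np.testing.assert_allclose(out.mats["chr1"], 3.0, rtol=1e-9)
        s = out.mats["chr1"].sum(1)
        assert s.std() / s.mean() < 1e-12

    def test_matches_independent_fixed_point_iteration(self, rng):
        dense = symmetric_random(4, rng)
        out = ice_normalize(matrix_from_dense(dense), tol=1e-10,
                            max_iter=10000, low_coverage_fraction=0.0,
                            low_coverage_floor=0.0)
        oracle = sinkhorn_oracle(dense)
        np.testing.assert_allclose(out.mats["chr1"], oracle, rtol=1e-6)

    def test_zero_row_masked_others_balanced(self, rng):
        dense = symmetric_random(8, rng)
        dense[3, :] = 0.0
        dense[:, 3] = 0.0
        out = ice_normalize(matrix_from_dense(dense), tol=1e-6,
                            low_coverage_fraction=0.0, low_coverage_floor=0.0)
        assert out.mask["chr1"][3]
        assert not out.mask["chr1"][[0, 1, 2, 4, 5, 6, 7]].any()
        s = out.mats["chr1"].sum(1)
        keep = ~out.mask["chr1"]
        assert s[keep].std() / s[keep].mean() < 1e-6

    def test_all_masked_raises(self):
        with pytest.raises(ValueError, match="no usable bins"):
            ice_normalize(matrix_from_dense(np.zeros((5, 5))))

    def test_idempotent_and_preserves_invariants(self, rng):
        dense = symmetric_random(60, rng)
        once = ice_normalize(matrix_from_dense(dense), tol=1e-8)
        twice = ice_normalize(once, tol=1e-8, low_coverage_fraction=0.0,
                              low_coverage_floor=0.0)
        np.testing.assert_allclose(twice.mats["chr1"], once.mats["chr1"],
                                   rtol=1e-4)
        once.check()  # symmetry, non-negativity, mask consistency

    def test_relative_floor_masks_depleted_bins(self, rng):
        dense = symmetric_random(50, rng)
        dense[10:15, :] *= 0.02
        dense[:, 10:15] *= 0.02
        dense[np.ix_(range(10, 15), range(10, 15))] /= 0.02
        out = ice_normalize(matrix_from_dense(dense))
        assert out.mask["chr1"][10:15].all()


# ---------------------------------------------------------------------------
# Distance decay / OE
# ---------------------------------------------------------------------------

class TestDecay:
    def test_toeplitz_decay_recovered_exactly(self):
        n = 12
        f = 10.0 / (1 + np.arange(n))
        dense = f[np.abs(np.subtract.outer(np.arange(n), np.arange(n)))]
        dec = expected_by_distance(matrix_from_dense(dense))
        np.testing.assert_allclose(dec.values["chr1"], f)
        oe = observed_over_expected(matrix_from_dense(dense), dec)
        np.testing.assert_allclose(oe.mats["chr1"], 1.0)

    def test_zero_matrix_gives_zero_decay_and_zero_oe(self):
        m = matrix_from_dense(np.zeros((7, 7)))
        dec = expected_by_distance(m)
        assert not dec.values["chr1"].any()
        oe = observed_over_expected(m, dec)  # 0/0 -> 0
        assert not oe.mats["chr1"].any()

    def test_random_matrix_matches_direct_diagonal_means(self, rng):
        dense = symmetric_random(30, rng)
        dec = expected_by_distance(matrix_from_dense(dense))
        for d in range(30):
            direct = np.mean([dense[i, i + d] for i in range(30 - d)])
            assert dec.values["chr1"][d] == pytest.approx(direct)

    def test_oe_is_direct_division(self, rng):
        dense = symmetric_random(15, rng)
        m = matrix_from_dense(dense)
        dec = expected_by_distance(m)
        oe = observed_over_expected(m, dec)
        i, j = 4, 11
        assert oe.mats["chr1"][i, j] == pytest.approx(
            dense[i, j] / dec.values["chr1"][j - i])

    def test_shape_mismatch_rejected(self, rng):
        m = matrix_from_dense(symmetric_random(10, rng))
        bad = expected_by_distance(matrix_from_dense(symmetric_random(11, rng)))
        with pytest.raises(ValueError):
            observed_over_expected(m, bad)


# ---------------------------------------------------------------------------
# Low-abundance filter
# ---------------------------------------------------------------------------

class TestFilter:
    def test_cutoff_is_ten_times_trans_mean_boundary_inclusive(self):
        # trans mean 0.0145687 -> cutoff 0.145687: the value at the cutoff
        # is kept, a value just below is removed
        dense = np.array([[0.0, 0.145687], [0.145687, 0.14]])
        dense[1, 1] = 0.14
        out = filter_low_contacts(matrix_from_dense(dense), 0.0145687)
        assert out.mats["chr1"][0, 1] == 0.145687
        assert out.mats["chr1"][1, 1] == 0.0
        assert out.state == "filtered"

    def test_zero_trans_mean_filters_nothing(self, rng):
        dense = symmetric_random(8, rng)
        out = filter_low_contacts(matrix_from_dense(dense), 0.0)
        np.testing.assert_array_equal(out.mats["chr1"], dense)

    def test_survivors_are_exactly_entries_at_or_above_cutoff(self, rng):
        dense = symmetric_random(25, rng, low=0.0, high=0.3)
        out = filter_low_contacts(matrix_from_dense(dense), 0.01)
        expected = np.where(dense >= 0.1, dense, 0.0)
        np.testing.assert_array_equal(out.mats["chr1"], expected)

    def test_monotone_in_trans_mean(self, rng):
        dense = symmetric_random(20, rng, low=0.0, high=1.0)
        m = matrix_from_dense(dense)
        lo = filter_low_contacts(m, 0.02).mats["chr1"] != 0
        hi = filter_low_contacts(m, 0.05).mats["chr1"] != 0
        assert not (hi & ~lo).any()  # raising trans_mean never adds entries

    def test_missing_trans_mean_errors(self, rng):
        with pytest.raises(ValueError, match="trans_mean"):
            filter_low_contacts(matrix_from_dense(symmetric_random(5, rng)))

    def test_stored_trans_mean_used_by_default(self, rng):
        dense = symmetric_random(6, rng, low=0.0, high=1.0)
        m = matrix_from_dense(dense, trans_mean=0.03)
        out = filter_low_contacts(m)
        np.testing.assert_array_equal(out.mats["chr1"],
                                      np.where(dense >= 0.3, dense, 0.0))
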