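"""Contour metrics against closed forms and brute-force oracles, plus the
Friedman / Wilcoxon-Holm statistics on hand-computed examples."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy import stats as sps

from fractalseg.metrics import (BinaryVolume, CaseMetrics, extract_surface,
                                friedman_across_strategies, hd95,
                                median_split_by_svr, nearest_rank_percentile,
                                pairwise_wilcoxon_holm, sdsc, svr, vdsc)


def _vol(voxels, spacing=(1, 1, 1)):
    return BinaryVolume(np.asarray(voxels, dtype=np.uint8), spacing)


def _cube(L, pad=1, spacing=(1, 1, 1)):
    side = L + 2 * pad
    v = np.zeros((side, side, side), dtype=np.uint8)
    v[pad:pad + L, pad:pad + L, pad:pad + L] = 1
    return BinaryVolume(v, spacing)


def brute_sdsc_hd95(A, B, tau):
    """Independent all-pairs oracle for the surface metrics."""
    sa = extract_surface(A).points
    sb = extract_surface(B).points
    D = cdist(sa, sb)
    da, db = D.min(axis=1), D.min(axis=0)
    s = ((da <= tau).sum() + (db <= tau).sum()) / (len(sa) + len(sb))
    pooled = np.sort(np.concatenate([da, db]))
    h = pooled[int(np.ceil(0.95 * len(pooled))) - 1]
    return float(s), float(h)


class TestVDSC:
    def test_identical_nonempty_is_one(self):
        A = _cube(3)
        assert vdsc(A, A) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((6, 6, 6)); a[0, 0, 0] = 1
        b = np.zeros((6, 6, 6)); b[5, 5, 5] = 1
        assert vdsc(_vol(a), _vol(b)) == 0.0

    def test_hand_counted_overlap(self):
        # |A| = 4, |B| = 4, |A ∩ B| = 2 -> 2*2/8 = 0.5
        a = np.zeros((4, 4, 4)); a[0, 0, :4] = 1
        b = np.zeros((4, 4, 4)); b[0, 0, 2:] = 1; b[0, 1, :2] = 1
        assert vdsc(_vol(a), _vol(b)) == 0.5

    def test_both_empty_is_one_by_convention(self):
        z = _vol(np.zeros((3, 3, 3)))
        assert vdsc(z, z) == 1.0

    def test_symmetry(self, rng):
        a = _vol(rng.random((6, 6, 6)) > 0.5)
        b = _vol(rng.random((6, 6, 6)) > 0.5)
        assert vdsc(a, b) == vdsc(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vdsc(_vol(np.zeros((3, 3, 3))), _vol(np.zeros((4, 4, 4))))


class TestSurfaceExtraction:
    def test_single_voxel_six_faces(self):
        v = np.zeros((3, 3, 3)); v[1, 1, 1] = 1
        cloud = extract_surface(_vol(v))
        assert len(cloud.points) == 6
        assert cloud.total_area == pytest.approx(6.0)
        # face centers sit half a mm off the voxel center along one axis
        d = np.abs(cloud.points - np.array([1.0, 1.0, 1.0]))
        np.testing.assert_allclose(np.sort(d, axis=1), [[0, 0, 0.5]] * 6)

    def test_solid_cube_area_6L2(self):
        assert extract_surface(_cube(10)).total_area == pytest.approx(600.0)

    def test_hollow_cube_adds_inner_faces_only(self):
        solid = _cube(10)
        hollow = np.array(solid.voxels)
        hollow[3:9, 3:9, 3:9] = 0
        outer = set(map(tuple, extract_surface(solid).points.round(6)))
        both = set(map(tuple, extract_surface(_vol(hollow)).points.round(6)))
        assert outer <= both
        assert len(both) > len(outer)

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            extract_surface(_vol(np.zeros((3, 3, 3))))


class TestSurfaceDice:
    def test_identical_is_one(self):
        A = _cube(4)
        assert sdsc(A, A, tau=0.5) == 1.0

    def test_huge_tolerance_is_one(self, rng):
        a = _vol(rng.random((5, 5, 5)) > 0.6)
        b = _vol(rng.random((5, 5, 5)) > 0.6)
        if a.count() and b.count():
            assert sdsc(a, b, tau=100.0) == 1.0

    def test_distant_single_voxels_zero(self):
        a = np.zeros((8, 8, 8)); a[1, 1, 1] = 1
        b = np.zeros((8, 8, 8)); b[6, 1, 1] = 1  # 5 mm apart at unit spacing
        assert sdsc(_vol(a), _vol(b), tau=1.0) == 0.0

    def test_monotone_in_tau(self, rng):
        a = _vol(rng.random((6, 6, 6)) > 0.5)
        b = _vol(rng.random((6, 6, 6)) > 0.5)
        if a.count() and b.count():
            vals = [sdsc(a, b, tau) for tau in (0.5, 1.0, 2.0, 4.0, 100.0)]
            assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))
            assert vals[-1] == 1.0


class TestHD95:
    def test_identical_zero(self):
        assert hd95(_cube(3), _cube(3)) == 0.0

    def test_single_voxels_five_mm(self):
        a = np.zeros((8, 8, 8)); a[1, 1, 1] = 1
        b = np.zeros((8, 8, 8)); b[6, 1, 1] = 1
        assert hd95(_vol(a), _vol(b)) == pytest.approx(5.0, abs=np.sqrt(3))

    def test_nearest_rank_oracle(self):
        assert nearest_rank_percentile(np.arange(1, 101), 95.0) == 95.0

    def test_le_exact_hausdorff_and_symmetric(self, rng):
        a = _vol(rng.random((6, 6, 6)) > 0.5)
        b = _vol(rng.random((6, 6, 6)) > 0.5)
        if a.count() and b.count():
            sa, sb = extract_surface(a).points, extract_surface(b).points
            D = cdist(sa, sb)
            exact_hausdorff = max(D.min(axis=1).max(), D.min(axis=0).max())
            assert hd95(a, b) <= exact_hausdorff + 1e-12
            assert hd95(a, b) == hd95(b, a)


class TestSVR:
    @pytest.mark.parametrize("L", [1, 5, 10, 20])
    def test_cube_closed_form(self, L):
        assert svr(_cube(L)) == pytest.approx(6.0 / L, rel=1e-12)

    def test_single_voxel(self):
        v = np.zeros((3, 3, 3)); v[1, 1, 1] = 1
        assert svr(_vol(v)) == pytest.approx(6.0)

    def test_spacing_scaling(self):
        v = np.zeros((6, 6, 6)); v[2:4, 2:4, 2:4] = 1
        s1 = svr(BinaryVolume(v.astype(np.uint8), (1, 1, 1)))
        s2 = svr(BinaryVolume(v.astype(np.uint8), (2, 2, 2)))
        assert s2 == pytest.approx(s1 / 2)


class TestBruteForceEquivalence:
    def test_random_volume_pairs_match_all_pairs_oracle(self, rng):
        """sdsc and hd95 agree exactly with the brute-force implementation on
        randomized small volumes (anisotropic spacing included)."""
        for trial in range(12):
            sp = tuple(rng.uniform(0.5, 2.5, size=3))
            a = rng.random((6, 7, 5)) > rng.uniform(0.4, 0.8)
            b = rng.random((6, 7, 5)) > rng.uniform(0.4, 0.8)
            if not (a.any() and b.any()):
                continue
            A, B = BinaryVolume(a.astype(np.uint8), sp), BinaryVolume(b.astype(np.uint8), sp)
            tau = rng.uniform(0.5, 3.0)
            bs, bh = brute_sdsc_hd95(A, B, tau)
            assert sdsc(A, B, tau) == pytest.approx(bs, abs=1e-12)
            assert hd95(A, B) == pytest.approx(bh, abs=1e-12)


def _cm(case_id, s, svr_value=0.5):
    return CaseMetrics(case_id, s, 0.8, 0.7, 2.0, svr_value)


class TestMedianSplit:
    def test_even_split_104(self):
        cases = [_cm(f"c{i:03d}", "x", svr_value=0.3 + 0.003 * i) for i in range(104)]
        simple, complex_ = median_split_by_svr(cases)
        assert len(simple) == len(complex_) == 52
        assert max(c.svr for c in simple) <= min(c.svr for c in complex_)

    def test_odd_split_puts_median_in_simple(self):
        cases = [_cm(f"c{i}", "x", svr_value=float(i)) for i in range(5)]
        simple, complex_ = median_split_by_svr(cases)
        assert len(simple) == 3 and len(complex_) == 2

    def test_all_equal_svr_tie_breaks_by_case_id(self):
        cases = [_cm(f"c{i}", "x", svr_value=0.4) for i in range(4)]
        s1 = median_split_by_svr(cases)
        s2 = median_split_by_svr(list(reversed(cases)))
        assert [c.case_id for c in s1[0]] == [c.case_id for c in s2[0]] == ["c0", "c1"]


class TestFriedman:
    def test_identical_columns_zero_statistic(self):
        X = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
        stat, p = friedman_across_strategies(X)
        assert stat == 0.0 and p == 1.0

    def test_constant_shift_two_strategies_hand_formula(self):
        # B = A + 1 for n = 10 cases, k = 2: all ranks identical -> chi2 = 10
        a = np.arange(10, dtype=float)
        X = np.stack([a, a + 1], axis=1)
        stat, p = friedman_across_strategies(X)
        assert stat == pytest.approx(10.0)
        assert p < 0.01

    def test_case_order_invariance(self, rng):
        X = rng.random((12, 4))
        s1, _ = friedman_across_strategies(X)
        s2, _ = friedman_across_strategies(X[rng.permutation(12)])
        assert s1 == pytest.approx(s2)

    def test_matches_scipy_for_three_groups(self, rng):
        X = rng.random((15, 3))
        stat, p = friedman_across_strategies(X)
        ref = sps.friedmanchisquare(X[:, 0], X[:, 1], X[:, 2])
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            friedman_across_strategies(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestWilcoxonHolm:
    def test_identical_pair_p_one_not_significant(self):
        X = np.tile(np.arange(8, dtype=float)[:, None], (1, 2))
        table = pairwise_wilcoxon_holm(X, ["a", "b"])
        assert table["p_holm"].iloc[0] == 1.0
        assert not table["significant"].iloc[0]

    def test_holm_step_down_hand_example(self):
        """Raw (0.01, 0.02, 0.04) with m = 3 adjusts to (0.03, 0.04, 0.04)."""
        from statsmodels.stats.multitest import multipletests
        _, adj, _, _ = multipletests([0.01, 0.02, 0.04], method="holm")
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])

    def test_adjusted_ge_raw(self, rng):
        X = rng.random((12, 4))
        table = pairwise_wilcoxon_holm(X)
        assert (table["p_holm"] >= table["p_raw"] - 1e-15).all()

    def test_detects_constructed_difference(self, rng):
        a = rng.random(20)
        X = np.stack([a, a + 0.3, a + rng.normal(0, 1e-3, 20)], axis=1)
        table = pairwise_wilcoxon_holm(X, ["a", "b", "c"])
        row = table[table["pair"] == "a vs b"].iloc[0]
        assert row["significant"]
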