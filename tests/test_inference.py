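"""Two-sample t maps, smoothness estimation, clusters and FWE correction."""
import numpy as np
import pytest

import ivimpipe as ip
from ivimpipe.inference import group_residuals, rft_correct
from ivimpipe.phantom import _unit_random_field

VOXEL = (3.75, 3.75, 5.0)


def _vol(x):
    return np.asarray(x, dtype=float).reshape(1, 1, 1)


def flood_fill_clusters(vol: np.ndarray, connectivity: int) -> list[set]:
    """Independent brute-force connected components by breadth-first search."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                n_nonzero = sum(v != 0 for v in (dx, dy, dz))
                if n_nonzero == 0:
                    continue
                if connectivity == 6 and n_nonzero > 1:
                    continue
                if connectivity == 18 and n_nonzero > 2:
                    continue
                offs.append((dx, dy, dz))
    todo = {tuple(idx) for idx in np.argwhere(vol)}
    comps = []
    while todo:
        seed = todo.pop()
        comp, queue = {seed}, [seed]
        while queue:
            x, y, z = queue.pop()
            for dx, dy, dz in offs:
                nb = (x + dx, y + dy, z + dz)
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


class TestVoxelwiseTTest:
    def test_identical_groups_give_zero_t(self):
        maps = [np.full((3, 3, 2), 1.7) + i for i in range(3)]
        t = ip.voxelwise_ttest(maps, maps)
        assert np.all(t.t == 0)

    def test_hand_computed_pooled_t(self):
        # A = {1,2,3}, B = {3,4,5}: pooled s^2 = 1, se = sqrt(2/3), t = -sqrt(6)
        t = ip.voxelwise_ttest([_vol(1), _vol(2), _vol(3)], [_vol(3), _vol(4), _vol(5)])
        assert t.t[0, 0, 0] == pytest.approx(-np.sqrt(6.0), abs=1e-12)
        assert t.df == 4

    def test_sign_flips_exactly_under_group_swap(self):
        rng = np.random.default_rng(0)
        A = [rng.normal(size=(4, 4, 3)) for _ in range(5)]
        B = [rng.normal(size=(4, 4, 3)) for _ in range(5)]
        t_ab = ip.voxelwise_ttest(A, B).t
        t_ba = ip.voxelwise_ttest(B, A).t
        np.testing.assert_allclose(t_ab, -t_ba, atol=1e-12)

    def test_invariant_to_subject_order_within_group(self):
        rng = np.random.default_rng(1)
        A = [rng.normal(size=(4, 4, 3)) for _ in range(5)]
        B = [rng.normal(size=(4, 4, 3)) for _ in range(5)]
        t1 = ip.voxelwise_ttest(A, B).t
        t2 = ip.voxelwise_ttest(A[::-1], B[2:] + B[:2]).t
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ip.voxelwise_ttest([_vol(1)], [_vol(2), _vol(3)])


class TestSmoothness:
    def test_white_noise_fwhm_near_one_voxel(self):
        rng = np.random.default_rng(2)
        resid = rng.normal(size=(12, 24, 24, 12))
        sm = ip.estimate_smoothness(resid, np.ones((24, 24, 12), bool))
        # derivative-variance formula gives sqrt(4 ln2 / 2) ~= 1.18 on white noise
        for f in sm.fwhm_voxels:
            assert 0.9 < f < 1.4

    def test_recovers_8mm_smoothing_within_15_percent(self):
        true_fwhm = np.array([8.0 / v for v in VOXEL])
        est = []
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            maps = [_unit_random_field((24, 24, 12), VOXEL, 8.0, rng) for _ in range(8)]
            resid = np.stack(maps) - np.stack(maps).mean(axis=0)
            sm = ip.estimate_smoothness(resid, np.ones((24, 24, 12), bool))
            est.append(sm.fwhm_voxels)
        mean_est = np.mean(est, axis=0)
        np.testing.assert_allclose(mean_est, true_fwhm, rtol=0.15)

    def test_resel_count_doubles_with_mask_volume(self):
        rng = np.random.default_rng(3)
        resid = rng.normal(size=(10, 16, 16, 16))
        half = np.zeros((16, 16, 16), bool)
        half[:8] = True
        sm_half = ip.estimate_smoothness(resid, half)
        # same residual roughness, double the volume
        full = np.ones((16, 16, 16), bool)
        sm_full = ip.estimate_smoothness(resid, full)
        ratio = sm_full.resel_count / sm_half.resel_count
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_flat_residuals_rejected(self):
        with pytest.raises(ValueError):
            ip.estimate_smoothness(np.zeros((4, 6, 6, 6)), np.ones((6, 6, 6), bool))


class TestFormClusters:
    def _tmap(self, t):
        return ip.TMap(t=t, df=10, mask=np.ones(t.shape, bool), voxel_size_mm=VOXEL)

    def test_zero_map_has_no_clusters(self):
        assert ip.form_clusters(self._tmap(np.zeros((6, 6, 4))), 2.0) == []

    def test_isolated_block_is_one_cluster(self):
        t = np.zeros((8, 8, 6))
        t[2:4, 2:4, 2:4] = 3.0
        clusters = ip.form_clusters(self._tmap(t), 2.0)
        assert len(clusters) == 1
        assert clusters[0].size_voxels == 8
        assert clusters[0].peak_t == 3.0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(5)
        for _ in range(30):
            t = rng.normal(size=(12, 12, 8))
            clusters = ip.form_clusters(self._tmap(t), 2.0, connectivity)
            got = {
                frozenset((int(i), int(j), int(k)) for i, j, k in np.argwhere(c.mask))
                for c in clusters
            }
            want = set(map(frozenset, flood_fill_clusters(t >= 2.0, connectivity)))
            assert got == want

    def test_clusters_partition_the_suprathreshold_set(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=(10, 10, 6))
        clusters = ip.form_clusters(self._tmap(t), 1.5)
        union = np.zeros(t.shape, bool)
        total = 0
        for c in clusters:
            assert not (union & c.mask).any()  # disjoint
            union |= c.mask
            total += c.size_voxels
        np.testing.assert_array_equal(union, t >= 1.5)
        assert total == np.count_nonzero(t >= 1.5)


class TestClusterPRft:
    smooth = ip.SmoothnessEstimate((2.1, 2.1, 1.6), 1000.0)

    def test_monotone_decreasing_in_size(self):
        ps = [
            ip.cluster_p_rft(k, self.smooth, 2.0, 20, 6912)[0]
            for k in (1, 5, 20, 80, 320)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_vanishing_size_saturates_at_the_cluster_count_limit(self):
        # as size -> 0 the extent tail -> 1 and p -> 1 - exp(-E[clusters]),
        # which is ~1 whenever many clusters are expected
        p1, _ = ip.cluster_p_rft(1, self.smooth, 2.0, 20, 6912)
        assert p1 > 0.99

    def test_smoother_field_gives_larger_p_at_fixed_size(self):
        rough = ip.SmoothnessEstimate((1.5, 1.5, 1.2), 6912 / (1.5 * 1.5 * 1.2))
        smooth = ip.SmoothnessEstimate((4.0, 4.0, 3.0), 6912 / (4.0 * 4.0 * 3.0))
        p_rough, _ = ip.cluster_p_rft(60, rough, 2.0, 20, 6912)
        p_smooth, _ = ip.cluster_p_rft(60, smooth, 2.0, 20, 6912)
        assert p_smooth > p_rough

    def test_low_threshold_attaches_warning(self):
        _, warn = ip.cluster_p_rft(10, self.smooth, 1.2, 20, 6912)
        assert warn


class TestClusterPPermutation:
    def test_exhaustive_minimum_attainable_p_is_one_twentieth(self):
        # n_A = n_B = 3 -> C(6,3) = 20 label arrangements
        rng = np.random.default_rng(7)
        base = rng.normal(size=(6, 6, 4)) * 0.01
        A = [base + 5.0 for _ in range(3)]  # overwhelming effect everywhere
        B = [base - 5.0 + 0.1 * rng.normal(size=base.shape) for _ in range(3)]
        clusters, null_max = ip.cluster_p_permutation(A, B, 2.0, n_perm=0)
        assert null_max.size == 19
        assert clusters[0].p_fwe == pytest.approx(1.0 / 20.0)

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(200 + seed)
            maps = [
                _unit_random_field((10, 10, 6), VOXEL, 8.0, rng) for _ in range(8)
            ]
            clusters, _ = ip.cluster_p_permutation(maps[:4], maps[4:], 1.8, n_perm=0)
            if clusters:
                ps.append(min(c.p_fwe for c in clusters))
        assert 0.25 < np.mean(ps) < 0.75

    def test_agrees_with_rft_on_cluster_ranking(self, tiny_spec):
        cohort = ip.generate_cohort(tiny_spec)
        fitted = [
            ip.fit_ivim_volume(ip.preprocess_series(d, fwhm_mm=8.0), method="segmented")
            for d in cohort.dwi
        ]
        pats = [m["dstar"] for m, s in zip(fitted, cohort.truth.subjects) if s.group == "patient"]
        ctls = [m["dstar"] for m, s in zip(fitted, cohort.truth.subjects) if s.group == "control"]
        perm_clusters, _ = ip.cluster_p_permutation(pats, ctls, 1.8, n_perm=0, seed=0)
        tmap = ip.voxelwise_ttest(pats, ctls, voxel_size_mm=VOXEL)
        rft_clusters = ip.form_clusters(tmap, 1.8)
        sm = ip.estimate_smoothness(group_residuals(pats, ctls), tmap.mask)
        rft_correct(rft_clusters, sm, tmap.df, int(tmap.mask.sum()))
        perm_order = [c.size_voxels for c in sorted(perm_clusters, key=lambda c: c.p_fwe)]
        rft_order = [c.size_voxels for c in sorted(rft_clusters, key=lambda c: c.p_fwe)]
        assert perm_order == rft_order


class TestIntersection:
    def test_identical_disjoint_nested(self):
        a = np.zeros((4, 4, 2), bool)
        a[:2] = True
        b = np.zeros_like(a)
        b[2:] = True
        nested = a.copy()
        nested[0] = False
        np.testing.assert_array_equal(ip.intersect_significant_clusters([a, a]), a)
        assert ip.intersect_significant_clusters([a, b]).sum() == 0
        np.testing.assert_array_equal(
            ip.intersect_significant_clusters([a, nested]), nested
        )

    def test_fewer_than_two_masks_rejected(self):
        with pytest.raises(ValueError):
            ip.intersect_significant_clusters([np.ones((2, 2, 2), bool)])

    def test_dice_of_identical_and_disjoint_masks(self):
        a = np.zeros((4, 4, 2), bool)
        a[:2] = True
        assert ip.dice(a, a) == 1.0
        assert ip.dice(a, ~a) == 0.0
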