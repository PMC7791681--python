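"""Group inference: GLM t maps, cluster labeling, TFCE, permutation FWE, spheres."""

import numpy as np
import pytest
from scipy import stats

from boldsv.groupstats import (
    GroupDesign,
    cluster_extent_fwe,
    glm_ttest,
    make_sphere_mask,
    tfce_permutation,
    tfce_transform,
)
from boldsv.volume import mni_like_affine


def make_design(rng, n_per=6, shape=(5, 5, 5), effect=0.0, covariates=None, seed_offset=0):
    n = 2 * n_per
    maps = rng.standard_normal((n,) + shape)
    maps[n_per:] += effect
    group = np.array([0.0] * n_per + [1.0] * n_per)
    return GroupDesign(
        z_maps=maps, group=group, covariates=covariates,
        mask=np.ones(shape, bool), affine=mni_like_affine(shape, 2.0),
    )


class TestGlmTtest:
    def test_identical_group_means_t_near_zero(self, rng):
        maps = rng.standard_normal((8, 4, 4, 4))
        # force both group means exactly equal voxel-wise
        maps[:4] -= maps[:4].mean(axis=0)
        maps[4:] -= maps[4:].mean(axis=0)
        d = GroupDesign(z_maps=maps, group=np.array([0.0] * 4 + [1.0] * 4),
                        mask=np.ones((4, 4, 4), bool))
        t, _ = glm_ttest(d)
        np.testing.assert_allclose(t, 0.0, atol=1e-8)

    def test_no_covariates_equals_pooled_two_sample_t(self, rng):
        d = make_design(rng, n_per=7)
        t_map, df = glm_ttest(d)
        assert df == 14 - 2
        # closed-form pooled two-sample t oracle at every voxel
        a = d.z_maps[:7].reshape(7, -1)
        b = d.z_maps[7:].reshape(7, -1)
        t_oracle, _ = stats.ttest_ind(b, a, axis=0, equal_var=True)
        np.testing.assert_allclose(t_map.ravel(), t_oracle, atol=1e-10)

    def test_covariate_collinear_with_group_rejected(self, rng):
        cov = np.array([0.0] * 6 + [1.0] * 6)[:, None]  # == group indicator
        d = make_design(rng, covariates=cov)
        with pytest.raises(ValueError, match="rank-deficient"):
            glm_ttest(d)

    def test_sex_coding_does_not_change_group_t(self, rng):
        sex = rng.integers(0, 2, 12).astype(float)
        d1 = make_design(rng, covariates=sex[:, None])
        d2 = GroupDesign(z_maps=d1.z_maps, group=d1.group,
                         covariates=(1.0 - sex)[:, None], mask=d1.mask)
        np.testing.assert_allclose(glm_ttest(d1)[0], glm_ttest(d2)[0], atol=1e-10)


class TestClusterExtent:
    def test_toy_1d_runs_labelled_by_extent(self, rng):
        # supra-threshold runs of lengths 3, 1, 2 along one axis
        shape = (12, 1, 1)
        n_per = 8
        maps = rng.standard_normal((2 * n_per,) + shape) * 0.1
        strong = [0, 1, 2, 5, 8, 9]  # runs {3},{1},{2}
        for v in strong:
            maps[n_per:, v, 0, 0] += 10.0
        d = GroupDesign(z_maps=maps, group=np.array([0.0] * n_per + [1.0] * n_per),
                        mask=np.ones(shape, bool))
        res = cluster_extent_fwe(d, n_perm=100, seed=0)
        assert sorted(c["extent"] for c in res.clusters) == [1, 2, 3]

    def test_null_design_rarely_significant(self, rng):
        d = make_design(rng, n_per=8, shape=(6, 6, 6))
        res = cluster_extent_fwe(d, n_perm=200, seed=1)
        assert all(c["p_fwe"] >= 1 / 201 for c in res.clusters)
        assert len(res.significant_clusters(0.01)) == 0

    def test_planted_effect_peak_inside_blob(self, rng):
        shape = (8, 8, 8)
        maps = rng.standard_normal((16,) + shape)
        blob = np.zeros(shape, bool)
        blob[2:5, 2:5, 2:5] = True
        maps[8:, blob] += 3.0
        d = GroupDesign(z_maps=maps, group=np.array([0.0] * 8 + [1.0] * 8),
                        mask=np.ones(shape, bool))
        res = cluster_extent_fwe(d, n_perm=200, seed=2)
        sig = res.significant_clusters(0.05)
        assert sig and blob[sig[0]["peak_ijk"]]

    def test_no_supra_threshold_voxels_empty_list(self, rng):
        maps = rng.standard_normal((12, 4, 4, 4)) * 1e-6
        maps[:6] += 0  # pure null, tiny scale
        d = GroupDesign(z_maps=maps, group=np.array([0.0] * 6 + [1.0] * 6),
                        mask=np.ones((4, 4, 4), bool))
        res = cluster_extent_fwe(d, height_p=1e-9, n_perm=100, seed=0)
        assert res.clusters == []

    def test_corrected_p_floor(self, rng):
        d = make_design(rng, effect=5.0)
        res = cluster_extent_fwe(d, n_perm=100, seed=0)
        assert all(c["p_fwe"] >= 1 / 101 for c in res.clusters)


def brute_force_tfce(stat, mask, E, H, dh):
    """Per-voxel threshold-summation oracle with BFS component search."""
    shape = stat.shape
    out = np.zeros(shape)
    for sign in (1.0, -1.0):
        tail = sign * stat
        tmax = tail[mask].max() if mask.any() else 0.0
        n_thr = int(np.floor(tmax / dh + 1e-12))
        for i in range(1, n_thr + 1):
            h = i * dh
            supra = (tail >= h) & mask
            seen = np.zeros(shape, bool)
            for idx in np.argwhere(supra):
                idx = tuple(idx)
                if seen[idx]:
                    continue
                # BFS over the 26-neighbourhood
                comp = [idx]
                seen[idx] = True
                queue = [idx]
                while queue:
                    cur = queue.pop()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            for dk in (-1, 0, 1):
                                if di == dj == dk == 0:
                                    continue
                                nb = (cur[0] + di, cur[1] + dj, cur[2] + dk)
                                if all(0 <= nb[a] < shape[a] for a in range(3)) \
                                        and supra[nb] and not seen[nb]:
                                    seen[nb] = True
                                    comp.append(nb)
                                    queue.append(nb)
                contrib = sign * len(comp) ** E * h**H * dh
                for v in comp:
                    out[v] += contrib
    return out


class TestTfce:
    def test_all_zero_map(self):
        mask = np.ones((4, 4, 4), bool)
        np.testing.assert_array_equal(tfce_transform(np.zeros((4, 4, 4)), mask), 0.0)

    def test_flat_single_blob_closed_form(self):
        shape = (8, 8, 8)
        stat = np.zeros(shape)
        stat[2:5, 2:5, 2:5] = 2.0  # extent N=27, height 2
        mask = np.ones(shape, bool)
        dh = 0.1
        out = tfce_transform(stat, mask, E=0.5, H=2.0, dh=dh)
        n_thr = int(np.floor(2.0 / dh + 1e-12))
        expected = sum(27**0.5 * (i * dh) ** 2 * dh for i in range(1, n_thr + 1))
        np.testing.assert_allclose(out[stat > 0], expected, rtol=1e-12)
        np.testing.assert_array_equal(out[stat == 0], 0.0)

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(3):
            stat = rng.standard_normal((6, 6, 6))
            mask = rng.random((6, 6, 6)) > 0.2
            dh = np.abs(stat[mask]).max() / 15
            ours = tfce_transform(stat, mask, E=0.5, H=2.0, dh=dh)
            oracle = brute_force_tfce(np.where(mask, stat, 0.0), mask, 0.5, 2.0, dh)
            np.testing.assert_allclose(ours, oracle, rtol=1e-8, atol=1e-12)

    def test_positive_rescale_scales_tfce_by_known_factor(self, rng):
        # scaling the map and dh by c multiplies TFCE by c^(H+1), so the
        # voxel ranking within a fixed-shape component is preserved
        shape = (6, 6, 6)
        stat = np.zeros(shape)
        stat[1:5, 1:5, 1:5] = rng.random((4, 4, 4)) + 0.5  # one connected blob
        mask = np.ones(shape, bool)
        # dh chosen off the exact-divisor boundary of max|stat|
        a = tfce_transform(stat, mask, H=2.0, dh=stat.max() / 40.7)
        b = tfce_transform(2.5 * stat, mask, H=2.0, dh=2.5 * stat.max() / 40.7)
        np.testing.assert_allclose(b, 2.5**3 * a, rtol=1e-10)
        sel = stat > 0
        ra = np.argsort(np.argsort(a[sel]))
        rb = np.argsort(np.argsort(b[sel]))
        assert np.array_equal(ra, rb)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tfce_transform(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool))


class TestTfcePermutation:
    def test_label_invariant_data_all_p_one(self, rng):
        # every subject carries the identical map: the statistic is exactly
        # zero under every labeling, so all FWE p must be 1
        maps = np.tile(rng.standard_normal((1, 4, 4, 4)), (8, 1, 1, 1))
        d = GroupDesign(z_maps=maps, group=np.array([0.0] * 4 + [1.0] * 4),
                        mask=np.ones((4, 4, 4), bool))
        res = tfce_permutation(d, n_perm=200, seed=0, n_steps=10)
        assert np.all(res.fwe_p_map >= 0.999)

    def test_exhaustive_enumeration_on_tiny_design(self, rng):
        d = make_design(rng, n_per=4, shape=(4, 4, 4), effect=2.0)
        res = tfce_permutation(d, n_perm=200, seed=0, n_steps=10)
        assert res.perm_mode == "exhaustive"
        assert res.n_permutations == 70  # C(8,4)
        # Monte-Carlo Freedman-Lane agrees within enumeration error
        d_cov = GroupDesign(z_maps=d.z_maps, group=d.group,
                            covariates=np.zeros((8, 1)) + rng.standard_normal((8, 1)),
                            mask=d.mask)
        res_mc = tfce_permutation(d_cov, n_perm=500, seed=1, n_steps=10)
        assert res_mc.perm_mode == "freedman-lane"
        pmin_ex = res.fwe_p_map[d.mask].min()
        pmin_mc = res_mc.fwe_p_map[d.mask].min()
        assert abs(pmin_ex - pmin_mc) < 0.15

    def test_planted_effect_detected(self, rng):
        shape = (5, 5, 5)
        maps = rng.standard_normal((16,) + shape)
        maps[8:, 1:4, 1:4, 1:4] += 3.0
        d = GroupDesign(z_maps=maps, group=np.array([0.0] * 8 + [1.0] * 8),
                        mask=np.ones(shape, bool))
        res = tfce_permutation(d, n_perm=300, seed=3, n_steps=20)
        assert res.fwe_p_map[d.mask].min() <= 0.05


class TestSphereMask:
    def enumerate_count(self, radius, voxel=2.0):
        m = int(np.ceil(radius / voxel)) + 1
        return sum(
            1
            for i in range(-m, m + 1)
            for j in range(-m, m + 1)
            for k in range(-m, m + 1)
            if voxel * np.sqrt(i * i + j * j + k * k) <= radius
        )

    def test_5mm_sphere_on_2mm_grid_is_81_voxels(self):
        affine = mni_like_affine((15, 15, 15), 2.0)
        mask = make_sphere_mask([[0, 0, 0]], (15, 15, 15), affine, 5.0)
        assert mask.sum() == self.enumerate_count(5.0) == 81

    def test_3mm_sphere_on_2mm_grid_matches_enumeration(self):
        affine = mni_like_affine((15, 15, 15), 2.0)
        mask = make_sphere_mask([[0, 0, 0]], (15, 15, 15), affine, 3.0)
        assert mask.sum() == self.enumerate_count(3.0) == 19

    def test_radius_zero_single_voxel(self):
        affine = mni_like_affine((7, 7, 7), 2.0)
        mask = make_sphere_mask([[0, 0, 0]], (7, 7, 7), affine, 0.0)
        assert mask.sum() == 1 and mask[3, 3, 3]

    def test_overlapping_union_smaller_than_sum(self):
        affine = mni_like_affine((15, 15, 15), 2.0)
        union = make_sphere_mask([[0, 0, 0], [2, 0, 0]], (15, 15, 15), affine, 5.0)
        assert union.sum() < 2 * 81

    def test_out_of_grid_center_rejected(self):
        affine = mni_like_affine((7, 7, 7), 2.0)
        with pytest.raises(ValueError, match="empty"):
            make_sphere_mask([[100, 100, 100]], (7, 7, 7), affine, 2.0)
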