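"""Group statistics and Monte-Carlo cluster-extent calibration."""

import numpy as np
import pytest
from scipy import ndimage, stats

from dmnconnect import (cluster_mean_z, extract_clusters,
                        monte_carlo_cluster_threshold, or_mask,
                        two_sample_t_map)
from dmnconnect.structures import StatMap, TemplateMap, default_affine

from conftest import flood_fill_clusters


def cube_mask(n):
    return np.ones((n, n, n), dtype=bool)


class TestTwoSampleT:
    def test_hand_oracle_pooled_variance(self):
        mask = cube_mask(2)
        a = np.array([np.full((2, 2, 2), v) for v in (1.0, 2.0, 3.0)])
        b = np.array([np.full((2, 2, 2), v) for v in (0.0, 1.0, 2.0)])
        out = two_sample_t_map(a, b, mask)
        assert out.df == 4
        np.testing.assert_allclose(out.values[mask], 1.224744871, atol=1e-8)

    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal((3, 2, 2, 2))
        out = two_sample_t_map(g, g.copy(), cube_mask(2))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_label_swap_negates_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((4, 3, 3, 3))
        b = rng.standard_normal((5, 3, 3, 3))
        ab = two_sample_t_map(a, b, cube_mask(3))
        ba = two_sample_t_map(b, a, cube_mask(3))
        np.testing.assert_allclose(ba.values, -ab.values, atol=1e-10)
        assert ab.df == 7

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            two_sample_t_map(np.ones((1, 2, 2, 2)), np.ones((3, 2, 2, 2)),
                             cube_mask(2))


class TestOrMask:
    def test_disjoint_union_identity_nesting(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[:1] = True          # 16 voxels
        b[2:] = True          # 32 voxels
        assert or_mask(a, b).sum() == 48
        np.testing.assert_array_equal(or_mask(a, a), a)
        nested = a.copy()
        nested[0, 0, 0] = False
        np.testing.assert_array_equal(or_mask(a, nested), a)

    def test_accepts_template_maps_and_checks_grids(self):
        a = TemplateMap(voxels=np.ones((3, 3, 3), bool))
        b = TemplateMap(voxels=np.zeros((3, 3, 3), bool))
        assert or_mask(a, b).sum() == 27
        with pytest.raises(ValueError):
            or_mask(np.ones((3, 3, 3), bool), np.ones((4, 4, 4), bool))


class TestClusterMeanZ:
    def test_examples_and_linearity(self):
        cluster = np.zeros((3, 1, 1), dtype=bool)
        cluster[:] = True
        z = np.array([1.0, 2.0, 6.0]).reshape(3, 1, 1)
        assert cluster_mean_z(z, cluster) == pytest.approx(3.0)
        assert cluster_mean_z(np.full((3, 1, 1), 4.2), cluster) == \
            pytest.approx(4.2)
        assert cluster_mean_z(2.5 * z, cluster) == pytest.approx(7.5)
        with pytest.raises(ValueError):
            cluster_mean_z(z, np.zeros((3, 1, 1), bool))


def make_stat(values, df=26, sided="two", mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones(values.shape, dtype=bool) if mask is None else mask
    return StatMap(values=values * mask, df=df, sided=sided, mask=mask)


class TestExtractClusters:
    def test_subthreshold_map_gives_empty_table(self):
        table = extract_clusters(make_stat(np.zeros((5, 5, 5))), 0.005, 1)
        assert len(table) == 0

    def test_two_blobs_extent_filter_and_peak(self):
        vals = np.zeros((12, 12, 12))
        vals[1, 1:3, 1:3] = 9.0                   # 4 voxels
        vals[6:8, 6:8, 6:8] = 9.0
        vals[7, 7, 7] = 11.0
        vals[6, 6, 7] = 0.0                       # 7-voxel blob
        table = extract_clusters(make_stat(vals), voxel_p=0.005,
                                 min_cluster_vox=5)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.size_voxels == 7
        assert (row.peak_i, row.peak_j, row.peak_k) == (7, 7, 7)
        assert row.peak_stat == pytest.approx(11.0)

    def test_cluster_volume_at_3mm_voxels(self):
        vals = np.zeros((10, 10, 10))
        vals[2:5, 2:6, 3] = 9.0                   # 12 voxels
        affine = default_affine((3.0, 3.0, 3.0), (10, 10, 10))
        table = extract_clusters(make_stat(vals), 0.005, 1, affine=affine)
        assert table.iloc[0].size_voxels == 12
        assert table.iloc[0].size_mm3 == pytest.approx(324.0)

    def test_per_group_cluster_mean_z_summaries(self):
        vals = np.zeros((6, 6, 6))
        vals[2:4, 2:4, 2] = 9.0
        cluster = vals > 0
        rng = np.random.default_rng(2)
        maps_a = rng.standard_normal((3, 6, 6, 6))
        maps_b = rng.standard_normal((2, 6, 6, 6))
        table = extract_clusters(make_stat(vals), 0.005, 1,
                                 subject_maps_by_group={"A": maps_a,
                                                        "B": maps_b})
        per_sub = [m[cluster].mean() for m in maps_a]
        assert table.iloc[0].z_mean_A == pytest.approx(np.mean(per_sub))
        assert table.iloc[0].z_sd_A == pytest.approx(np.std(per_sub, ddof=1))

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.standard_normal((12, 12, 12)) * 4.0
            stat = make_stat(vals)
            crit = stats.t.ppf(1 - 0.005 / 2, stat.df)
            supra = np.abs(vals) > crit
            expected = [s for s in flood_fill_clusters(supra, connectivity)
                        if s >= 3]
            table = extract_clusters(stat, 0.005, 3,
                                     connectivity=connectivity)
            assert sorted(table.size_voxels.tolist(), reverse=True) == expected


class TestMonteCarloThreshold:
    def test_extreme_voxel_p_gives_unit_extent(self):
        res = monte_carlo_cluster_threshold(cube_mask(12), fwhm_mm=6.0,
                                            voxel_p=1e-12, n_iter=200, seed=0)
        assert res.min_cluster_vox == 1
        assert "no suprathreshold voxel" in res.note

    def test_unsmoothed_matches_independent_voxel_oracle(self):
        """With FWHM 0 the null is iid; a brute-force simulation written
        directly against numpy must give the same extent within 1 voxel."""
        mask = cube_mask(8)
        voxel_p, alpha, n_iter = 0.05, 0.05, 800
        res = monte_carlo_cluster_threshold(mask, fwhm_mm=0.0,
                                            voxel_p=voxel_p, alpha=alpha,
                                            sided="two", n_iter=n_iter,
                                            seed=5)
        rng = np.random.default_rng(123)
        crit = stats.norm.ppf(1 - voxel_p / 2)
        maxima = []
        struct = ndimage.generate_binary_structure(3, 1)
        for _ in range(n_iter):
            z = rng.standard_normal(mask.shape)
            z = (z - z[mask].mean()) / z[mask].std()
            labels, n = ndimage.label((np.abs(z) > crit) & mask, struct)
            maxima.append(np.bincount(labels.ravel())[1:].max()
                          if n else 0)
        maxima = np.array(maxima)
        oracle = 1
        while (maxima >= oracle).mean() > alpha:
            oracle += 1
        assert abs(res.min_cluster_vox - oracle) <= 1

    def test_achieved_alpha_within_bound_and_seeded(self):
        mask = cube_mask(14)
        a = monte_carlo_cluster_threshold(mask, 6.0, 0.005, 0.05,
                                          n_iter=300, seed=9)
        b = monte_carlo_cluster_threshold(mask, 6.0, 0.005, 0.05,
                                          n_iter=300, seed=9)
        assert a.min_cluster_vox == b.min_cluster_vox
        assert a.alpha_achieved <= 0.05
        np.testing.assert_array_equal(a.max_cluster_null, b.max_cluster_null)

    def test_monotonic_in_voxel_p_and_fwhm(self):
        mask = cube_mask(14)
        strict = monte_carlo_cluster_threshold(mask, 6.0, 0.001, 0.05,
                                               n_iter=300, seed=4)
        loose = monte_carlo_cluster_threshold(mask, 6.0, 0.01, 0.05,
                                              n_iter=300, seed=4)
        assert strict.min_cluster_vox <= loose.min_cluster_vox
        narrow = monte_carlo_cluster_threshold(mask, 3.0, 0.005, 0.05,
                                               n_iter=300, seed=4)
        wide = monte_carlo_cluster_threshold(mask, 9.0, 0.005, 0.05,
                                             n_iter=300, seed=4)
        assert narrow.min_cluster_vox <= wide.min_cluster_vox

    @pytest.mark.parametrize("bad", [dict(voxel_p=0.0), dict(alpha=1.5),
                                     dict(n_iter=50)])
    def test_parameter_validation(self, bad):
        kwargs = dict(voxel_p=0.005, alpha=0.05, n_iter=300)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            monte_carlo_cluster_threshold(cube_mask(6), 6.0, **kwargs)
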