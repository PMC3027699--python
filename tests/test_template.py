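"""Group template construction and goodness-of-fit selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dmnconnect import (ComponentSet, TemplateMap, build_template,
                        goodness_of_fit, one_sample_t_map, select_best_fit,
                        select_candidate_by_correlation)


def cube_mask(n=5):
    return np.ones((n, n, n), dtype=bool)


def stat_from_values(per_subject_voxel_values, mask=None):
    """Stack per-subject constant maps holding the given voxel values."""
    vals = np.asarray(per_subject_voxel_values, dtype=float)
    mask = cube_mask(2) if mask is None else mask
    maps = np.array([np.full(mask.shape, v) for v in vals])
    # vary one corner voxel so the map is not globally degenerate
    return maps, mask


class TestOneSampleT:
    def test_hand_oracle(self):
        mask = cube_mask(2)
        maps = np.array([np.full(mask.shape, v) for v in (1.0, 2.0, 3.0)])
        out = one_sample_t_map(maps, mask)
        assert out.df == 2
        np.testing.assert_allclose(out.values[mask], 2.0 / (1.0 / np.sqrt(3)),
                                   atol=1e-10)

    def test_zero_mean_gives_zero_t(self):
        mask = cube_mask(2)
        maps = np.array([np.full(mask.shape, v) for v in (-1.0, 0.0, 1.0)])
        out = one_sample_t_map(maps, mask)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_df_for_27_subjects(self):
        rng = np.random.default_rng(0)
        maps = rng.standard_normal((27, 3, 3, 3))
        out = one_sample_t_map(maps, cube_mask(3))
        assert out.df == 26

    def test_zero_variance_voxel_flagged_not_nan(self):
        mask = cube_mask(2)
        maps = np.zeros((3, 2, 2, 2))
        maps[:, 0, 0, 0] = [1.0, 2.0, 3.0]
        out = one_sample_t_map(maps, mask)
        assert np.isfinite(out.values).all()
        assert out.flagged_zero_variance[1, 1, 1]
        assert not out.flagged_zero_variance[0, 0, 0]

    def test_fewer_than_two_maps_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t_map(np.ones((1, 2, 2, 2)), cube_mask(2))


class TestBuildTemplate:
    def test_all_zero_map_gives_empty_template_with_warning(self, caplog):
        mask = cube_mask(4)
        stat = one_sample_t_map(np.zeros((3, 4, 4, 4)), mask)
        with caplog.at_level("WARNING", logger="dmnconnect.template"):
            tmpl = build_template(stat, voxel_p=0.005, min_cluster_vox=1)
        assert tmpl.size == 0
        assert "no suprathreshold cluster" in caplog.text

    def test_one_sided_threshold_at_df_26(self):
        # critical t for one-sided p<0.005 at df 26 is 2.7787
        mask = np.ones((3, 1, 1), dtype=bool)
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((27, 3, 1, 1)) * 0.01
        stat = one_sample_t_map(maps, mask)
        stat.values[0, 0, 0] = 2.8
        stat.values[1, 0, 0] = 2.7
        stat.values[2, 0, 0] = -5.0          # one-sided: negatives excluded
        tmpl = build_template(stat, voxel_p=0.005, min_cluster_vox=1)
        assert tmpl.voxels[0, 0, 0]
        assert not tmpl.voxels[1, 0, 0]
        assert not tmpl.voxels[2, 0, 0]

    def test_cluster_extent_filter(self):
        mask = cube_mask(8)
        vals = np.zeros((8, 8, 8))
        vals[0:1, 0:2, 0:2] = 10.0           # 4-voxel cluster
        vals[4:6, 4:6, 4:6] = 10.0           # 8-voxel cluster
        stat = one_sample_t_map(
            np.array([vals * 0.9, vals, vals * 1.1]), mask)
        tmpl = build_template(stat, voxel_p=0.005, min_cluster_vox=5)
        assert tmpl.voxels[5, 5, 5]
        assert not tmpl.voxels[0, 0, 0]
        assert tmpl.size == 8


class TestGoodnessOfFit:
    def setup_method(self):
        self.mask = np.zeros((5, 1, 1), dtype=bool)
        self.mask[:5] = True
        tmpl = np.zeros((5, 1, 1), dtype=bool)
        tmpl[:2] = True
        self.template = TemplateMap(voxels=tmpl)

    def test_hand_oracle(self):
        z = np.array([2.0, 4.0, 1.0, 0.0, -1.0]).reshape(5, 1, 1)
        assert goodness_of_fit(z, self.template, self.mask) == pytest.approx(3.0)

    def test_constant_map_scores_zero(self):
        z = np.full((5, 1, 1), 7.7)
        assert goodness_of_fit(z, self.template, self.mask) == pytest.approx(0.0)

    def test_indicator_scores_one(self):
        z = self.template.voxels.astype(float)
        assert goodness_of_fit(z, self.template, self.mask) == pytest.approx(1.0)

    def test_empty_inside_or_outside_rejected(self):
        z = np.zeros((5, 1, 1))
        with pytest.raises(ValueError):
            goodness_of_fit(z, TemplateMap(voxels=np.zeros((5, 1, 1), bool)),
                            self.mask)
        with pytest.raises(ValueError):
            goodness_of_fit(z, TemplateMap(voxels=self.mask.copy()), self.mask)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(-5, 5),
           st.floats(0.1, 10))
    def test_shift_invariance_and_positive_homogeneity(self, seed, c, a):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((5, 1, 1))
        base = goodness_of_fit(z, self.template, self.mask)
        shifted = goodness_of_fit(z + c, self.template, self.mask)
        scaled = goodness_of_fit(a * z, self.template, self.mask)
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(a * base, rel=1e-9, abs=1e-9)


def component_set_from_maps(maps, mask):
    maps = np.asarray(maps, dtype=float)
    return ComponentSet(maps=maps, courses=np.zeros((10, len(maps))),
                        mask=mask, n_requested=len(maps),
                        n_realized=len(maps), explained_variance=1.0)


class TestSelectBestFit:
    def test_template_replica_component_wins(self):
        rng = np.random.default_rng(2)
        mask = cube_mask(4)
        tmpl = np.zeros((4, 4, 4), dtype=bool)
        tmpl[:2, :2, :2] = True
        template = TemplateMap(voxels=tmpl)
        maps = [rng.standard_normal((4, 4, 4)) * 0.1 for _ in range(3)]
        maps[1] = tmpl.astype(float) * 3.0
        fit = select_best_fit(component_set_from_maps(maps, mask), template)
        assert fit.best_index == 1
        assert fit.scores[fit.best_index] >= fit.scores[fit.second_index]

    def test_tie_broken_by_lower_index(self):
        mask = cube_mask(3)
        tmpl = np.zeros((3, 3, 3), dtype=bool)
        tmpl[0] = True
        the_map = tmpl.astype(float)
        fit = select_best_fit(
            component_set_from_maps([the_map, the_map.copy()], mask),
            TemplateMap(voxels=tmpl))
        assert fit.best_index == 0
        assert fit.second_index == 1
        assert fit.tie_broken

    def test_candidate_by_correlation_picks_planted(self):
        rng = np.random.default_rng(3)
        mask = cube_mask(6)
        prior = np.zeros((6, 6, 6))
        prior[2:5, 2:5, 2:5] = 1.0
        maps = [rng.standard_normal((6, 6, 6)) for _ in range(4)]
        maps[2] = prior + 0.1 * rng.standard_normal((6, 6, 6))
        comps = component_set_from_maps(maps, mask)
        assert select_candidate_by_correlation(comps, prior) == 2


class TestSelectionFairness:
    def test_effect_free_cohorts_score_equally(self):
        """Identical selection code on two effect-free cohorts: mean
        best-fit scores differ non-significantly in >= 90/100 replicate
        datasets (two-sample t, alpha 0.05)."""
        rng = np.random.default_rng(99)
        mask = cube_mask(8)
        tmpl = np.zeros((8, 8, 8), dtype=bool)
        tmpl[2:6, 2:6, 2:6] = True
        template = TemplateMap(voxels=tmpl)
        signal = tmpl.astype(float)
        non_sig = 0
        for _ in range(100):
            scores = {"A": [], "B": []}
            for cohort, n in (("A", 7), ("B", 6)):
                for _ in range(n):
                    maps = [signal * rng.uniform(0.8, 1.2)
                            + 0.3 * rng.standard_normal((8, 8, 8))
                            for _ in range(2)]
                    maps[1] = rng.standard_normal((8, 8, 8))
                    comps = component_set_from_maps(maps, mask)
                    fit = select_best_fit(comps, template)
                    scores[cohort].append(fit.scores[fit.best_index])
            p = stats.ttest_ind(scores["A"], scores["B"]).pvalue
            non_sig += p > 0.05
        assert non_sig >= 90
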