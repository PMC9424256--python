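import numpy as np
import pytest
from scipy import special

import probatlas as pa
from probatlas.atlas_build import round_half_up

from conftest import full_mask, make_map


def t_crit_oracle(p, dof):
    """Independent inverse-incomplete-beta route to the one-sided t critical
    value (avoids the isf used by the implementation)."""
    x = special.betaincinv(dof / 2, 0.5, 2 * p)
    return np.sqrt(dof * (1 - x) / x)


def brute_force_top_k(values, mask, k):
    """Exhaustive oracle: sort (value desc, index asc), take first k."""
    idx = np.flatnonzero(mask)
    ranked = sorted(idx, key=lambda v: (-values[v], v))
    out = np.zeros(values.size, bool)
    out[ranked[:k]] = True
    return out


class TestTopFraction:
    def test_top_one_of_ten(self, line_grid):
        smap = make_map(line_grid, [5, 4, 3, 2, 1, 0, -1, -2, -3, -4])
        out = pa.top_fraction_binarize(smap, full_mask(line_grid), 0.10)
        np.testing.assert_array_equal(out.membership,
                                      [1, 0, 0, 0, 0, 0, 0, 0, 0, 0])

    def test_constant_map_ties_break_by_scan_order(self, line_grid):
        smap = make_map(line_grid, np.full(10, 2.0))
        out = pa.top_fraction_binarize(smap, full_mask(line_grid), 0.2)
        np.testing.assert_array_equal(out.membership,
                                      [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])

    def test_fraction_one_returns_mask(self, tiny_grid, rng):
        smap = make_map(tiny_grid, rng.normal(size=125))
        mask = pa.BinaryMap(tiny_grid, rng.random(125) < 0.5)
        out = pa.top_fraction_binarize(smap, mask, 1.0)
        np.testing.assert_array_equal(out.membership, mask.membership)

    def test_zero_k_errors(self, line_grid):
        smap = make_map(line_grid, np.arange(10.0))
        mask = pa.BinaryMap(line_grid, np.arange(10) < 2)
        with pytest.raises(pa.SelectionError):
            pa.top_fraction_binarize(smap, mask, 0.1)  # k = round(0.2) = 0

    def test_nan_in_mask_errors(self, line_grid):
        vals = np.arange(10.0)
        vals[3] = np.nan
        with pytest.raises(pa.SelectionError):
            pa.top_fraction_binarize(make_map(line_grid, vals),
                                     full_mask(line_grid), 0.5)

    def test_round_half_up(self):
        assert round_half_up(2.5) == 3
        assert round_half_up(2.4) == 2
        assert round_half_up(0.5) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = pa.VolumeGrid((10, 10, 10), np.diag([2.0, 2, 2, 1]))
        vals = np.round(rng.normal(size=1000), 1)  # coarse values force ties
        mask = rng.random(1000) < 0.7
        smap = make_map(grid, vals)
        f = 0.13
        k = round_half_up(f * mask.sum())
        out = pa.top_fraction_binarize(smap, pa.BinaryMap(grid, mask), f)
        np.testing.assert_array_equal(out.membership,
                                      brute_force_top_k(vals, mask, k))


class TestSurfacePooling:
    def test_top_fraction_pools_hemispheres(self):
        """Selecting over the concatenated LH+RH vertex vector preserves
        asymmetry: with stronger left values, most of the top 10% is left."""
        dom = pa.SurfaceDomain(left=100, right=100)
        rng = np.random.default_rng(2)
        vals = np.r_[rng.normal(1.0, 0.5, 100), rng.normal(0.0, 0.5, 100)]
        smap = pa.StatMap("s1", dom, vals, kind="t")
        mask = pa.BinaryMap(dom, np.ones(200, bool))
        out = pa.top_fraction_binarize(smap, mask, 0.10)
        assert out.count == 20
        left, right, _ = pa.hemisphere_masks(dom)
        assert (out.membership & left.membership).sum() > \
               (out.membership & right.membership).sum()
        atlas = pa.build_atlas([out])
        assert atlas.laterality.iloc[0] > 0.5


class TestThresholdBinarize:
    def test_dof100_p001_selects_two(self, line_grid):
        vals = [1, 2, 3.5, 4, 0, 0, 0, 0, 0, 0]
        mask = pa.BinaryMap(line_grid, np.arange(10) < 4)
        smap = make_map(line_grid, vals, kind="t", dof=100)
        out = pa.threshold_binarize(smap, mask, 0.001)
        assert out.count == 2
        # critical value from the independent beta-function oracle
        assert pa.t_critical(0.001, 100) == pytest.approx(
            t_crit_oracle(0.001, 100), abs=1e-9
        )

    def test_p_half_selects_about_half_of_null(self, rng):
        grid = pa.VolumeGrid((10, 10, 10), np.diag([2.0, 2, 2, 1]))
        # simulated t-noise: true null t-values at dof=30
        vals = rng.standard_t(30, size=1000)
        smap = make_map(grid, vals, kind="t", dof=30)
        out = pa.threshold_binarize(smap, full_mask(grid), 0.5)
        assert 400 < out.count < 600

    def test_all_nonpositive_gives_empty(self, line_grid):
        smap = make_map(line_grid, -np.arange(10.0), kind="t", dof=50)
        out = pa.threshold_binarize(smap, full_mask(line_grid), 0.01)
        assert out.count == 0  # empty allowed, unlike top_fraction

    def test_missing_dof_errors(self, line_grid):
        smap = make_map(line_grid, np.arange(10.0), kind="t", dof=None)
        with pytest.raises(pa.SelectionError):
            pa.threshold_binarize(smap, full_mask(line_grid), 0.01)


class TestBuildAtlas:
    def test_disjoint_selections_average_to_half(self, line_grid):
        rule = pa.SelectionRule(mode="top_fraction", fraction=0.2)
        m1 = pa.BinaryMap(line_grid, np.arange(10) < 2, rule=rule, subject="a")
        m2 = pa.BinaryMap(line_grid, np.arange(10) >= 8, rule=rule, subject="b")
        atlas = pa.build_atlas([m1, m2])
        np.testing.assert_allclose(atlas.values[[0, 1, 8, 9]], 0.5)
        np.testing.assert_allclose(atlas.values[2:8], 0.0)

    def test_identical_maps_give_zero_one_values(self, line_grid):
        m = pa.BinaryMap(line_grid, np.arange(10) < 3, subject="a")
        atlas = pa.build_atlas([pa.BinaryMap(line_grid, m.membership, subject=s)
                                for s in "abcde"])
        assert set(np.unique(atlas.values)) <= {0.0, 1.0}

    def test_values_times_n_are_integers(self, tiny_grid, rng):
        members = [
            pa.BinaryMap(tiny_grid, rng.random(125) < 0.3, subject=f"s{i}")
            for i in range(7)
        ]
        atlas = pa.build_atlas(members)
        scaled = atlas.values * atlas.n_subjects
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-12)

    def test_mask_mean_equals_fraction(self, tiny_grid, rng):
        """Conservation: each subject contributes exactly k ones, so the
        mask-mean of the atlas is k/|mask| = f up to k's rounding."""
        mask = full_mask(tiny_grid)
        f = 0.12
        members = [
            pa.top_fraction_binarize(
                make_map(tiny_grid, rng.normal(size=125), subject=f"s{i}"), mask, f
            )
            for i in range(9)
        ]
        atlas = pa.build_atlas(members, mask=mask)
        k = round_half_up(f * 125)
        assert atlas.values[mask.membership].mean() == pytest.approx(k / 125)
        assert abs(atlas.values[mask.membership].mean() - f) <= 1 / 125

    def test_mixed_rules_rejected(self, line_grid):
        r1 = pa.SelectionRule(mode="top_fraction", fraction=0.2)
        r2 = pa.SelectionRule(mode="fixed_p", p=0.01)
        m1 = pa.BinaryMap(line_grid, np.arange(10) < 2, rule=r1)
        m2 = pa.BinaryMap(line_grid, np.arange(10) < 2, rule=r2)
        with pytest.raises(pa.ProbatlasError):
            pa.build_atlas([m1, m2])

    def test_laterality_table(self, tiny_grid):
        x = tiny_grid.world_coords()[:, 0]
        sel = np.zeros(125, bool)
        left_idx = np.flatnonzero(x < 0)[:3]
        right_idx = np.flatnonzero(x > 0)[:1]
        sel[left_idx] = True
        sel[right_idx] = True
        atlas = pa.build_atlas([pa.BinaryMap(tiny_grid, sel, subject="s1")])
        assert atlas.laterality["s1"] == pytest.approx(0.75)


class TestAtlasSummary:
    def test_single_subject_hemisphere_max_in_01(self, tiny_grid, rng):
        mask = full_mask(tiny_grid)
        m = pa.top_fraction_binarize(make_map(tiny_grid, rng.normal(size=125)),
                                     mask, 0.1)
        summ = pa.atlas_summary(pa.build_atlas([m], mask=mask))
        assert summ.lh_max in (0.0, 1.0)
        assert summ.rh_max in (0.0, 1.0)


class TestStabilityCurve:
    def _maps(self, grid, rng, n, identical=False):
        base = rng.normal(size=grid.n_voxels)
        out = []
        for i in range(n):
            vals = base if identical else base + rng.normal(size=grid.n_voxels)
            out.append(make_map(grid, vals, subject=f"s{i}"))
        return out

    def test_identical_subjects_give_r_one(self, tiny_grid, rng):
        maps = self._maps(tiny_grid, rng, 10, identical=True)
        rule = pa.SelectionRule(mode="top_fraction", fraction=0.1)
        curve = pa.stability_curve(maps, rule, full_mask(tiny_grid),
                                   sizes=[2, 5], n_boot=4, seed=0)
        np.testing.assert_allclose(curve["mean_r"], 1.0)

    def test_full_cohort_size_gives_r_one(self, tiny_grid, rng):
        maps = self._maps(tiny_grid, rng, 8)
        rule = pa.SelectionRule(mode="top_fraction", fraction=0.1)
        curve = pa.stability_curve(maps, rule, full_mask(tiny_grid),
                                   sizes=[8], n_boot=3, seed=0)
        assert curve.loc[0, "mean_r"] == pytest.approx(1.0)

    def test_curve_nondecreasing_on_average(self, rng):
        grid = pa.VolumeGrid((8, 8, 8), np.diag([4.0, 4, 4, 1]))
        maps = self._maps(grid, rng, 40)
        rule = pa.SelectionRule(mode="top_fraction", fraction=0.1)
        curve = pa.stability_curve(maps, rule, full_mask(grid),
                                   sizes=[3, 10, 25], n_boot=30, seed=5)
        assert curve["mean_r"].is_monotonic_increasing

    def test_constant_atlas_errors(self, line_grid):
        maps = [make_map(line_grid, np.arange(10.0), subject=f"s{i}")
                for i in range(4)]
        rule = pa.SelectionRule(mode="top_fraction", fraction=1.0)
        with pytest.raises(pa.ProbatlasError):
            pa.stability_curve(maps, rule, full_mask(line_grid),
                               sizes=[2], n_boot=2, seed=0)
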