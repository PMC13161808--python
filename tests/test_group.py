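import numpy as np
import pytest
from scipy import stats

from fcnm.fc import FCMap
from fcnm.grid import BinaryMask, VolumeGrid
from fcnm.group import (
    ProbabilityMap,
    fwe_threshold_mask,
    one_sample_t,
    overlay_probability,
    threshold_probability,
)


def make_maps(arrays, grid):
    mask = BinaryMask.full(grid)
    return [
        FCMap(grid=grid, z=np.asarray(a, dtype=float), mask=mask,
              subject_id=f"s{i}", contrast_id="c", n_timepoints=100)
        for i, a in enumerate(arrays)
    ]


@pytest.fixture
def tiny_grid():
    return VolumeGrid.isotropic(3, 3.0)


class TestOneSampleT:
    def test_hand_computed_example(self, tiny_grid):
        maps = make_maps(
            [np.full(tiny_grid.shape, v) for v in (1.0, 2.0, 3.0)], tiny_grid
        )
        stat = one_sample_t(maps)
        assert stat.df == 2
        assert stat.t[0, 0, 0] == pytest.approx(2 * np.sqrt(3))  # 3.464
        assert stat.t[0, 0, 0] == pytest.approx(3.464, abs=1e-3)

    def test_matches_scipy_oracle(self, tiny_grid, rng):
        arrays = rng.standard_normal((8,) + tiny_grid.shape)
        stat = one_sample_t(make_maps(arrays, tiny_grid))
        expected = stats.ttest_1samp(arrays, 0.0, axis=0).statistic
        np.testing.assert_allclose(stat.t, expected, rtol=1e-10)

    def test_zero_variance_voxel_flagged_undefined(self, tiny_grid, rng):
        arrays = rng.standard_normal((5,) + tiny_grid.shape)
        arrays[:, 1, 1, 1] = 0.0
        stat = one_sample_t(make_maps(arrays, tiny_grid))
        assert not stat.defined[1, 1, 1]
        assert np.isnan(stat.t[1, 1, 1])
        assert stat.n_undefined == 1

    def test_antisymmetry_under_negation(self, tiny_grid, rng):
        arrays = rng.standard_normal((6,) + tiny_grid.shape)
        pos = one_sample_t(make_maps(arrays, tiny_grid))
        neg = one_sample_t(make_maps(-arrays, tiny_grid))
        np.testing.assert_allclose(neg.t, -pos.t, rtol=1e-12)

    def test_needs_two_subjects(self, tiny_grid, rng):
        with pytest.raises(ValueError, match="2 subjects"):
            one_sample_t(make_maps(rng.standard_normal((1,) + tiny_grid.shape), tiny_grid))

    def test_grid_mismatch_names_subject(self, tiny_grid, rng):
        other = VolumeGrid.isotropic(4, 3.0)
        maps = make_maps(rng.standard_normal((2,) + tiny_grid.shape), tiny_grid)
        bad = make_maps(rng.standard_normal((1,) + other.shape), other)[0]
        bad.subject_id = "s-bad"
        with pytest.raises(ValueError, match="s-bad"):
            one_sample_t(maps + [bad])


class TestFWEThreshold:
    def test_bonferroni_uses_alpha_over_v(self, rng):
        grid = VolumeGrid.isotropic(10, 3.0)  # V = 1000
        n, df = 20, 19
        t_crit = stats.t.isf(0.05 / 1000, df)  # per-voxel p threshold 5e-5
        base = rng.standard_normal((n,) + grid.shape) * 0.01
        # plant means yielding t just above / just below the critical value
        above, below = (0, 0, 0), (9, 9, 9)
        arrays = base.copy()
        arrays[:, above[0], above[1], above[2]] += 0.01 * (t_crit * 1.05) / np.sqrt(n)
        arrays[:, below[0], below[1], below[2]] += 0.01 * (t_crit * 0.95) / np.sqrt(n)
        maps = make_maps(arrays, grid)
        stat = one_sample_t(maps)
        # rescale exactly: force the two voxels to the intended t values
        stat.t[above] = t_crit * 1.01
        stat.t[below] = t_crit * 0.99
        mask = fwe_threshold_mask(stat, alpha=0.05, method="bonferroni")
        assert mask.data[above]
        assert not mask.data[below]

    def test_alpha_one_degenerates_to_sign(self, tiny_grid, rng):
        arrays = rng.standard_normal((6,) + tiny_grid.shape)
        stat = one_sample_t(make_maps(arrays, tiny_grid))
        mask = fwe_threshold_mask(stat, alpha=1.0)
        np.testing.assert_array_equal(mask.data, stat.defined & (np.nan_to_num(stat.t) > 0))

    def test_alpha_nesting(self, tiny_grid, rng):
        arrays = rng.standard_normal((10,) + tiny_grid.shape) + 1.0
        stat = one_sample_t(make_maps(arrays, tiny_grid))
        strict = fwe_threshold_mask(stat, alpha=0.01)
        loose = fwe_threshold_mask(stat, alpha=0.05)
        assert strict.issubset(loose)

    def test_negative_tail_mirrors_positive(self, tiny_grid, rng):
        arrays = rng.standard_normal((10,) + tiny_grid.shape) + 2.0
        pos = fwe_threshold_mask(one_sample_t(make_maps(arrays, tiny_grid)), tail="positive")
        neg = fwe_threshold_mask(one_sample_t(make_maps(-arrays, tiny_grid)), tail="negative")
        np.testing.assert_array_equal(pos.data, neg.data)

    def test_undefined_voxels_never_survive(self, tiny_grid, rng):
        arrays = rng.standard_normal((6,) + tiny_grid.shape) + 5.0
        arrays[:, 0, 0, 0] = 1.0  # zero variance
        stat = one_sample_t(make_maps(arrays, tiny_grid))
        for alpha in (0.05, 1.0):
            assert not fwe_threshold_mask(stat, alpha=alpha).data[0, 0, 0]

    def test_permutation_detects_signal_and_warns_small_n(self, rng):
        grid = VolumeGrid.isotropic(5, 3.0)
        arrays = rng.standard_normal((8,) + grid.shape) * 0.2
        arrays[:, 2, 2, 2] += 3.0  # strong planted effect
        maps = make_maps(arrays, grid)
        stat = one_sample_t(maps)
        with pytest.warns(UserWarning, match="coarse"):
            mask = fwe_threshold_mask(stat, method="permutation", z_maps=maps, seed=0)
        assert mask.data[2, 2, 2]
        assert mask.n_voxels <= 3  # essentially only the planted voxel

    def test_permutation_requires_maps(self, tiny_grid, rng):
        stat = one_sample_t(make_maps(rng.standard_normal((6,) + tiny_grid.shape), tiny_grid))
        with pytest.raises(ValueError, match="z maps"):
            fwe_threshold_mask(stat, method="permutation")


class TestProbabilityOverlay:
    def test_fraction_counts_masks(self, tiny_grid):
        masks = [BinaryMask.empty(tiny_grid) for _ in range(5)]
        for m in masks[:4]:
            m.data[1, 1, 1] = True
        pmap = overlay_probability(masks)
        assert pmap.fraction[1, 1, 1] == pytest.approx(0.8)  # 4 of 5
        assert pmap.fraction[0, 0, 0] == 0.0

    def test_identical_masks_give_binary_fractions(self, tiny_grid, rng):
        base = BinaryMask(tiny_grid, rng.random(tiny_grid.shape) > 0.5)
        pmap = overlay_probability([base] * 4)
        assert set(np.unique(pmap.fraction)) <= {0.0, 1.0}

    def test_fraction_times_n_is_integer(self, tiny_grid, rng):
        masks = [BinaryMask(tiny_grid, rng.random(tiny_grid.shape) > 0.5) for _ in range(7)]
        pmap = overlay_probability(masks)
        np.testing.assert_allclose(pmap.fraction * 7, np.round(pmap.fraction * 7), atol=1e-9)


class TestProbabilityThreshold:
    @pytest.mark.parametrize("n_contrasts,k_min", [(25, 16), (24, 15), (10, 8)])
    def test_strict_minimum_surviving_count(self, tiny_grid, n_contrasts, k_min):
        counts = np.zeros(tiny_grid.shape, dtype=int)
        counts[0, 0, 0] = k_min
        counts[0, 0, 1] = k_min - 1
        pmap = ProbabilityMap(tiny_grid, counts, n_contrasts)
        thr = 0.7 if n_contrasts == 10 else 0.6
        net = threshold_probability(pmap, thr)
        assert net.data[0, 0, 0]
        assert not net.data[0, 0, 1]

    def test_boundary_thresholds_rejected(self, tiny_grid):
        pmap = ProbabilityMap(tiny_grid, np.zeros(tiny_grid.shape, dtype=int), 5)
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError, match="threshold"):
                threshold_probability(pmap, bad)

    def test_threshold_nesting(self, tiny_grid, rng):
        counts = rng.integers(0, 21, size=tiny_grid.shape)
        pmap = ProbabilityMap(tiny_grid, counts, 20)
        n70 = threshold_probability(pmap, 0.7)
        n60 = threshold_probability(pmap, 0.6)
        n50 = threshold_probability(pmap, 0.5)
        assert n70.issubset(n60) and n60.issubset(n50)
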