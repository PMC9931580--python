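import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cytoniche.masks import (
    adaptive_refine,
    curate_mask,
    enhance_contrast,
    median_filter_3x3,
    quantize_levels,
    remove_small_blobs,
    select_foreground,
)
from cytoniche.model import MarkerSpec


class TestMedianFilter:
    def test_constant_unchanged(self):
        raster = np.full((8, 8), 7.0)
        np.testing.assert_array_equal(median_filter_3x3(raster), raster)

    def test_isolated_hot_pixel_suppressed(self):
        raster = np.zeros((9, 9))
        raster[4, 4] = 100.0
        assert median_filter_3x3(raster)[4, 4] == 0.0

    def test_matches_brute_force_with_edge_replication(self, rng):
        raster = rng.integers(0, 50, size=(5, 5)).astype(float)
        padded = np.pad(raster, 1, mode="edge")
        expected = np.empty_like(raster)
        for i in range(5):
            for j in range(5):
                expected[i, j] = np.median(padded[i : i + 3, j : j + 3])
        np.testing.assert_array_equal(median_filter_3x3(raster), expected)


def brute_force_two_means_boundary(values):
    """Exhaustive 1-D 2-means: best split threshold by within-class SSE."""
    v = np.sort(values.ravel())
    best, best_cut = np.inf, None
    for cut in range(1, len(v)):
        lo, hi = v[:cut], v[cut:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best:
            best, best_cut = sse, (v[cut - 1] + v[cut]) / 2
    return best_cut


class TestQuantizeLevels:
    def test_six_distinct_values_one_level_each(self):
        vals = np.array([0, 10, 20, 30, 40, 50])
        raster = np.repeat(vals, 6).reshape(6, 6)
        lr = quantize_levels(raster, k=6, seed=0)
        np.testing.assert_allclose(lr.group_centres, vals)
        assert lr.n_levels == 6
        # each distinct value is its own ascending level
        np.testing.assert_array_equal(np.unique(lr.levels), np.arange(1, 7))

    def test_constant_channel_degenerates_to_single_level(self):
        with pytest.warns(UserWarning, match="distinct"):
            lr = quantize_levels(np.full((4, 4), 3.0), k=6, seed=0)
        assert lr.n_levels == 1
        assert (lr.levels == 1).all()

    def test_bimodal_split_matches_exhaustive_oracle(self, rng):
        low = rng.normal(10, 1.0, 400)
        high = rng.normal(60, 1.0, 400)
        raster = np.concatenate([low, high]).reshape(40, 20)
        lr = quantize_levels(raster, k=2, seed=0)
        boundary = lr.group_centres.mean()
        oracle = brute_force_two_means_boundary(raster)
        assert abs(boundary - oracle) < 1.0

    def test_deterministic_given_seed(self, rng):
        raster = rng.gamma(2.0, 5.0, size=(30, 30))
        a = quantize_levels(raster, seed=3)
        b = quantize_levels(raster, seed=3)
        np.testing.assert_array_equal(a.levels, b.levels)


class TestSelectForeground:
    def test_level6_selects_everything(self, rng):
        lr = quantize_levels(rng.uniform(0, 100, (20, 20)), k=6, seed=0)
        assert select_foreground(lr, 6).all()

    def test_level1_selects_only_brightest_group(self):
        vals = np.array([0, 10, 20, 30, 40, 50])
        raster = np.repeat(vals, 6).reshape(6, 6)
        lr = quantize_levels(raster, k=6, seed=0)
        fg = select_foreground(lr, 1)
        np.testing.assert_array_equal(fg, raster == 50)

    def test_out_of_range_level(self, rng):
        lr = quantize_levels(rng.uniform(0, 1, (8, 8)), k=6, seed=0)
        with pytest.raises(ValueError):
            select_foreground(lr, 0)
        with pytest.raises(ValueError):
            select_foreground(lr, 7)

    def test_nested_in_level(self, rng):
        """Foreground grows monotonically with the level parameter."""
        for _ in range(5):
            lr = quantize_levels(rng.uniform(0, 100, (15, 15)), k=6, seed=0)
            prev = select_foreground(lr, 1)
            for level in range(2, 7):
                cur = select_foreground(lr, level)
                assert (prev <= cur).all()
                prev = cur


def flood_fill_components(mask):
    """Naive 8-connected component enumeration (stack-based flood fill)."""
    visited = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not visited[i, j]:
                stack, comp = [(i, j)], []
                visited[i, j] = True
                while stack:
                    a, b = stack.pop()
                    comp.append((a, b))
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            na, nb = a + da, b + db
                            if 0 <= na < h and 0 <= nb < w and mask[na, nb] and not visited[na, nb]:
                                visited[na, nb] = True
                                stack.append((na, nb))
                comps.append(comp)
    return comps


class TestRemoveSmallBlobs:
    def test_area_threshold(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0, :3] = True  # area 3
        mask[5:10, 5:15] = True  # area 50
        out = remove_small_blobs(mask, min_area=10)
        assert not out[0, :3].any()
        assert out[5:10, 5:15].all()

    def test_min_area_one_is_identity(self, rng):
        mask = rng.random((15, 15)) < 0.3
        np.testing.assert_array_equal(remove_small_blobs(mask, 1), mask)

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(5):
            mask = rng.random((18, 18)) < 0.35
            expected = np.zeros_like(mask)
            for comp in flood_fill_components(mask):
                if len(comp) >= 6:
                    for a, b in comp:
                        expected[a, b] = True
            np.testing.assert_array_equal(remove_small_blobs(mask, 6), expected)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(arrays(bool, (12, 12)), st.integers(1, 10))
    def test_idempotent(self, mask, min_area):
        once = remove_small_blobs(mask, min_area)
        np.testing.assert_array_equal(remove_small_blobs(once, min_area), once)


class TestAdaptiveRefine:
    def test_empty_mask_stays_empty(self, rng):
        channel = rng.uniform(0, 10, (32, 32))
        out = adaptive_refine(channel, np.zeros((32, 32), dtype=bool))
        assert not out.any()

    def test_result_subset_of_input_mask(self, rng):
        channel = rng.uniform(0, 10, (32, 32))
        mask = rng.random((32, 32)) < 0.5
        out = adaptive_refine(channel, mask)
        assert (out <= mask).all()

    def test_equals_elementwise_and_of_operands(self, rng):
        channel = rng.gamma(2.0, 3.0, (48, 48))
        mask = rng.random((48, 48)) < 0.6
        out = adaptive_refine(channel, mask, sensitivity=0.4)
        adaptive_alone = adaptive_refine(channel, np.ones_like(mask), sensitivity=0.4)
        np.testing.assert_array_equal(out, mask & adaptive_alone)


class TestEnhanceContrast:
    def test_full_range_is_identity(self, rng):
        channel = rng.uniform(0, 100, (16, 16))
        np.testing.assert_allclose(enhance_contrast(channel, 0, 100), channel)

    def test_outlier_clipped_to_high_percentile(self, rng):
        channel = rng.uniform(0, 10, (50, 50))
        channel[0, 0] = 1e6
        out = enhance_contrast(channel, 1, 99)
        assert out[0, 0] == out.max()
        assert np.isclose(out.max(), channel.max())  # rescaled back to range
        # the outlier no longer dominates: second-largest is now equal to it
        assert np.sort(out.ravel())[-2] > 0.9 * out.max()

    def test_interior_rank_order_preserved(self, rng):
        from scipy.stats import spearmanr

        channel = rng.uniform(0, 100, (20, 20))
        out = enhance_contrast(channel, 5, 95)
        lo, hi = np.percentile(channel, [5, 95])
        interior = (channel > lo) & (channel < hi)
        rho = spearmanr(channel[interior], out[interior]).statistic
        assert rho == pytest.approx(1.0)

    def test_constant_channel_warns(self):
        with pytest.warns(UserWarning):
            out = enhance_contrast(np.full((4, 4), 2.0), 1, 99)
        np.testing.assert_array_equal(out, np.full((4, 4), 2.0))


class TestCurateMask:
    spec = MarkerSpec("M", foreground_level=5, min_blob_area=5)

    def planted_channel(self, rng, shape=(120, 120)):
        channel = rng.exponential(0.3, shape)
        truth = np.zeros(shape, dtype=bool)
        yy, xx = np.indices(shape)
        for cy, cx in [(30, 30), (60, 90), (90, 45)]:
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= 100
            truth |= disc
        channel[truth] += rng.lognormal(3.0, 0.5, truth.sum())
        return channel, truth

    def test_all_zero_channel_gives_empty_mask(self):
        with pytest.warns(UserWarning):
            mask = curate_mask(np.zeros((32, 32)), self.spec, seed=0)
        assert not mask.any()

    def test_recovers_planted_regions(self, rng):
        channel, truth = self.planted_channel(rng)
        mask = curate_mask(channel, self.spec, seed=0)
        sensitivity = (mask & truth).sum() / truth.sum()
        fpr = (mask & ~truth).sum() / (~truth).sum()
        assert sensitivity >= 0.95
        assert fpr <= 0.02

    def test_equals_manual_step_composition(self, rng):
        channel, _ = self.planted_channel(rng)
        mask = curate_mask(channel, self.spec, seed=11)
        work = median_filter_3x3(channel.astype(float))
        lr = quantize_levels(work, k=6, seed=11)
        manual = remove_small_blobs(select_foreground(lr, 5), 5)
        np.testing.assert_array_equal(mask, manual)

    def test_shift_invariant_without_enhancement(self, rng):
        channel, _ = self.planted_channel(rng)
        a = curate_mask(channel, self.spec, seed=2)
        b = curate_mask(channel + 17.5, self.spec, seed=2)
        np.testing.assert_array_equal(a, b)
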