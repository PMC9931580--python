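import numpy as np
import pandas as pd
import pytest

from cytoniche.lineage import (
    DEFAULT_SUBTYPE_RULES,
    apply_subtype_rules,
    assign_lineages,
    build_cell_table,
    majority_vectors,
    normalize_for_display,
    summarize_expression,
    zscore_cluster_means,
)
from cytoniche.model import (
    UNDEFINED,
    ChannelStack,
    ConfigurationError,
    LineageHierarchy,
    MaskSet,
    SegmentationMask,
)


def seg_from_array(arr):
    return SegmentationMask("img", np.asarray(arr, dtype=np.int64))


class TestMajorityVectors:
    def test_direct_pixel_counts(self):
        labels = np.zeros((4, 4), dtype=np.int64)
        labels[0, 0:4] = 1  # 4-pixel cell
        mask_a = np.zeros((4, 4), dtype=bool)
        mask_a[0, 0:3] = True  # covers 3 of them
        mask_b = np.zeros((4, 4), dtype=bool)
        mask_b[0, 3] = True  # covers 1
        ms = MaskSet("img", {"A": mask_a, "B": mask_b})
        mv = majority_vectors(seg_from_array(labels), ms, ["A", "B"])
        assert mv.loc[1, "A"] == 3
        assert mv.loc[1, "B"] == 1
        assert mv.loc[1, "area_px"] == 4

    def test_cell_outside_all_masks_is_zero_vector(self):
        labels = np.zeros((4, 4), dtype=np.int64)
        labels[2, 2] = 1
        ms = MaskSet("img", {"A": np.zeros((4, 4), dtype=bool)})
        mv = majority_vectors(seg_from_array(labels), ms, ["A"])
        assert mv.loc[1, "A"] == 0

    def test_matches_per_pixel_double_loop(self, rng):
        """Vectorized counts equal a naive loop over every pixel."""
        for _ in range(10):
            labels = rng.integers(0, 6, size=(12, 12)).astype(np.int64)
            masks = {m: rng.random((12, 12)) < 0.4 for m in ("A", "B", "C")}
            mv = majority_vectors(seg_from_array(labels), MaskSet("img", masks), ["A", "B", "C"])
            for cell in np.unique(labels[labels > 0]):
                for m in ("A", "B", "C"):
                    count = 0
                    for i in range(12):
                        for j in range(12):
                            if labels[i, j] == cell and masks[m][i, j]:
                                count += 1
                    assert mv.loc[cell, m] == count


class TestAssignLineages:
    hierarchy = LineageHierarchy.from_pairs([("B_lin", ["B"]), ("A_lin", ["A"])])

    def frame(self, rows):
        df = pd.DataFrame(rows, columns=["A", "B"])
        df["area_px"] = 10
        return df

    def test_strict_maximum_beats_priority(self):
        out = assign_lineages(self.frame([[3, 1]]), self.hierarchy)
        assert out.iloc[0] == "A_lin"

    def test_tie_goes_to_rank_priority(self):
        out = assign_lineages(self.frame([[2, 2]]), self.hierarchy)
        assert out.iloc[0] == "B_lin"

    def test_all_zero_is_undefined(self):
        out = assign_lineages(self.frame([[0, 0]]), self.hierarchy)
        assert out.iloc[0] == UNDEFINED

    def test_missing_marker_is_configuration_error(self):
        bad = LineageHierarchy.from_pairs([("X_lin", ["X"])])
        with pytest.raises(ConfigurationError, match="X"):
            assign_lineages(self.frame([[1, 0]]), bad)

    def test_multi_marker_lineage_scores_by_max_not_sum(self):
        hier = LineageHierarchy.from_pairs([("AB_lin", ["A", "B"]), ("C_lin", ["C"])])
        df = pd.DataFrame({"A": [3], "B": [3], "C": [4], "area_px": [10]})
        # sum would give AB_lin 6 > 4; max gives 3 < 4 -> C_lin
        assert assign_lineages(df, hier).iloc[0] == "C_lin"

    def test_storage_order_of_markers_is_irrelevant(self, rng):
        df = pd.DataFrame(
            rng.integers(0, 5, size=(30, 2)), columns=["A", "B"]
        )
        df["area_px"] = 9
        a = assign_lineages(df, self.hierarchy)
        b = assign_lineages(df[["B", "A", "area_px"]], self.hierarchy)
        assert (a == b).all()

    def test_partition_property(self, rng):
        df = pd.DataFrame(rng.integers(0, 3, size=(50, 2)), columns=["A", "B"])
        df["area_px"] = 8
        out = assign_lineages(df, self.hierarchy)
        counts = out.value_counts()
        assert counts.sum() == 50

    def test_growing_winning_marker_never_flips_assignment(self, rng):
        df = pd.DataFrame(rng.integers(0, 6, size=(40, 2)), columns=["A", "B"])
        df["area_px"] = 12
        base = assign_lineages(df, self.hierarchy)
        grown = df.copy()
        for i, lin in enumerate(base):
            if lin == "A_lin":
                grown.loc[grown.index[i], "A"] += 5
            elif lin == "B_lin":
                grown.loc[grown.index[i], "B"] += 5
        regrown = assign_lineages(grown, self.hierarchy)
        defined = base != UNDEFINED
        assert (base[defined] == regrown[defined]).all()


class TestSummarizeExpression:
    def test_two_pixel_cell_mean(self):
        labels = np.zeros((2, 2), dtype=np.int64)
        labels[0, 0] = labels[0, 1] = 1
        channel = np.array([[4.0, 6.0], [9.0, 9.0]])
        stack = ChannelStack("img", channel[None], ["M"])
        out = summarize_expression(seg_from_array(labels), stack)
        assert out.loc[1, "expr_M"] == 5.0

    def test_constant_channel_gives_constant_means(self, rng):
        labels = rng.integers(0, 4, size=(10, 10)).astype(np.int64)
        stack = ChannelStack("img", np.full((1, 10, 10), 3.5), ["M"])
        out = summarize_expression(seg_from_array(labels), stack)
        assert (out["expr_M"] == 3.5).all()

    def test_matches_masked_mean_loop(self, rng):
        labels = rng.integers(0, 5, size=(15, 15)).astype(np.int64)
        pixels = rng.uniform(0, 50, size=(2, 15, 15))
        stack = ChannelStack("img", pixels, ["M1", "M2"])
        out = summarize_expression(seg_from_array(labels), stack)
        for cell in np.unique(labels[labels > 0]):
            sel = labels == cell
            assert out.loc[cell, "expr_M1"] == pytest.approx(pixels[0][sel].mean())
            assert out.loc[cell, "expr_M2"] == pytest.approx(pixels[1][sel].mean())

    def test_centroid_is_pixel_mean(self):
        labels = np.zeros((5, 5), dtype=np.int64)
        labels[1, 1] = labels[1, 3] = 1
        stack = ChannelStack("img", np.zeros((1, 5, 5)), ["M"])
        out = summarize_expression(seg_from_array(labels), stack)
        assert out.loc[1, "centroid_x_um"] == 2.0  # columns 1 and 3
        assert out.loc[1, "centroid_y_um"] == 1.0


class TestSubtypeRules:
    def make_majority(self, p2y12, cd163, mpo, area=20):
        return pd.DataFrame(
            {"P2Y12": [p2y12], "CD163": [cd163], "MPO": [mpo], "area_px": [area]}
        )

    def test_mpo_positive_m1_mdm(self):
        flags = apply_subtype_rules(
            pd.Series(["macrophage"]), self.make_majority(0, 0, 10), DEFAULT_SUBTYPE_RULES
        )
        assert flags[0] == frozenset({"MDM", "M1-like", "MPO_pos"})

    def test_p2y12_positive_is_microglia(self):
        flags = apply_subtype_rules(
            pd.Series(["macrophage"]), self.make_majority(10, 0, 0), DEFAULT_SUBTYPE_RULES
        )
        assert "microglia" in flags[0] and "MDM" not in flags[0]

    def test_rules_scoped_to_lineage(self):
        flags = apply_subtype_rules(
            pd.Series(["tumour"]), self.make_majority(0, 20, 0), DEFAULT_SUBTYPE_RULES
        )
        assert flags[0] == frozenset()

    def test_unknown_marker_raises(self):
        from cytoniche.lineage import SubtypeRule

        with pytest.raises(ConfigurationError, match="NOPE"):
            apply_subtype_rules(
                pd.Series(["macrophage"]),
                self.make_majority(0, 0, 0),
                [SubtypeRule("NOPE", frozenset({"macrophage"}), "x", None)],
            )

    def test_positivity_threshold_is_quarter_of_area(self):
        # 4/20 = 0.2 < 0.25 -> negative; 5/20 = 0.25 -> positive
        neg = apply_subtype_rules(
            pd.Series(["macrophage"]), self.make_majority(4, 0, 0), DEFAULT_SUBTYPE_RULES
        )
        pos = apply_subtype_rules(
            pd.Series(["macrophage"]), self.make_majority(5, 0, 0), DEFAULT_SUBTYPE_RULES
        )
        assert "MDM" in neg[0] and "microglia" in pos[0]


class TestDisplayNormalization:
    def test_all_equal_maps_to_one(self):
        np.testing.assert_allclose(normalize_for_display(np.full(10, 5.0)), 1.0)

    def test_percentile_and_clipping(self):
        values = np.arange(101, dtype=float)
        out = normalize_for_display(values, 95)
        assert out[95] == 1.0
        assert out[100] == 1.0  # clipped
        assert out[50] == pytest.approx(50 / 95)

    def test_zscored_cluster_means_sum_to_zero(self, rng):
        means = pd.DataFrame(rng.uniform(0, 1, size=(5, 3)), columns=list("abc"))
        z = zscore_cluster_means(means)
        np.testing.assert_allclose(z.sum(axis=0), 0.0, atol=1e-12)

    def test_two_cluster_hand_z(self):
        means = pd.DataFrame({"m": [1.0, 3.0]})
        z = zscore_cluster_means(means)
        np.testing.assert_allclose(z["m"], [-np.sqrt(0.5), np.sqrt(0.5)])


class TestEndToEndPhenotyping:
    def test_planted_lineages_recovered(self, small_config, rendered_image):
        from cytoniche.masks import curate_mask

        stack, seg, truth = rendered_image
        panel = small_config.panel()
        ms = MaskSet(
            stack.image_id,
            {s.name: curate_mask(stack.channel(s.name), s, seed=0) for s in panel.markers},
        )
        table = build_cell_table(stack, seg, ms, small_config.hierarchy())
        accuracy = (table["lineage"].to_numpy() == truth["type"].to_numpy()).mean()
        assert accuracy >= 0.9
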