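"""Raster model and spatial pre-processing."""

import numpy as np
import pandas as pd
import pytest

from vector_enm.raster import (
    EnvStack,
    distance_to,
    extract_values,
    one_hot_encode,
    pearson_correlation_matrix,
    resample_layer,
)
from vector_enm.reference import brute_force_distance_to

from conftest import make_layer


class TestResample:
    def test_mean_aggregation_of_fine_grid(self):
        # 2 m cells aggregated to 10 m: each output cell is the 5x5 block mean
        vals = np.arange(100, dtype=float).reshape(10, 10)
        layer = make_layer(vals, cell_size=2.0)
        out = resample_layer(layer, 10.0)
        assert out.shape == (2, 2)
        assert out.cell_size == 10.0
        expected = vals.reshape(2, 5, 2, 5).swapaxes(1, 2).mean(axis=(2, 3))
        np.testing.assert_allclose(out.values, expected)

    def test_constant_layer_stays_constant(self):
        layer = make_layer(np.full((8, 8), 7.0), cell_size=5.0)
        out = resample_layer(layer, 20.0)
        np.testing.assert_array_equal(out.values, np.full((2, 2), 7.0))

    def test_categorical_majority(self):
        vals = np.ones((4, 4), dtype=int)
        vals[0, 0] = vals[0, 1] = vals[1, 0] = 2  # 13 cells of 1, 3 of 2
        layer = make_layer(vals, kind="categorical", cell_size=10.0,
                           labels={1: "a", 2: "b"})
        out = resample_layer(layer, 40.0)
        assert out.values[0, 0] == 1

    def test_non_integer_ratio_rejected(self):
        layer = make_layer(np.zeros((4, 4)), cell_size=3.0)
        with pytest.raises(ValueError, match="3"):
            resample_layer(layer, 10.0)

    def test_global_mean_preserved_without_nodata(self):
        rng = np.random.default_rng(0)
        vals = rng.random((40, 40))
        out = resample_layer(make_layer(vals, cell_size=1.0), 4.0)
        assert abs(out.values.mean() - vals.mean()) < 1e-12

    def test_nodata_propagation(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2, :2] = True          # whole first block nodata
        mask[0, 2] = True            # partial nodata in second block
        out = resample_layer(make_layer(vals, mask=mask, cell_size=1.0), 2.0)
        assert out.nodata_mask[0, 0]
        assert not out.nodata_mask[0, 1]
        expected = np.mean([vals[0, 3], vals[1, 2], vals[1, 3]])
        assert out.values[0, 1] == pytest.approx(expected)


class TestOneHot:
    def test_one_indicator_per_code_partition(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(1, 4, size=(6, 6))
        mask = rng.random((6, 6)) < 0.2
        layers = one_hot_encode(make_layer(vals, kind="categorical", mask=mask,
                                           labels={1: "a", 2: "b", 3: "c"}))
        assert len(layers) == len(np.unique(vals[~mask]))
        total = sum(l.values for l in layers)
        np.testing.assert_array_equal(total[~mask], 1.0)
        assert {l.name for l in layers} <= {"layer__a", "layer__b", "layer__c"}

    def test_single_category_all_ones(self):
        layers = one_hot_encode(make_layer(np.ones((3, 3), dtype=int),
                                           kind="categorical"))
        assert len(layers) == 1
        np.testing.assert_array_equal(layers[0].values, 1.0)

    def test_continuous_input_rejected(self):
        with pytest.raises(ValueError, match="categorical"):
            one_hot_encode(make_layer(np.zeros((2, 2))))


class TestDistanceTo:
    def test_zero_on_category_positive_elsewhere(self):
        vals = np.zeros((6, 6), dtype=int)
        vals[2, 3] = 1
        out = distance_to(make_layer(vals, kind="categorical"), 1)
        assert out.values[2, 3] == 0.0
        off = out.values[vals == 0]
        assert (off > 0).all()

    def test_center_to_corner_geometry(self):
        vals = np.zeros((3, 3), dtype=int)
        vals[1, 1] = 1
        out = distance_to(make_layer(vals, kind="categorical", cell_size=10.0), 1)
        assert out.values[0, 0] == pytest.approx(10 * np.sqrt(2))
        assert out.values[0, 1] == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(3, 13)), int(rng.integers(3, 13)))
        vals = rng.integers(0, 4, size=shape)
        mask = rng.random(shape) < 0.15
        if not ((vals == 1) & ~mask).any():
            vals[0, 0], mask[0, 0] = 1, False
        layer = make_layer(vals, kind="categorical", mask=mask, cell_size=7.5)
        out = distance_to(layer, 1)
        oracle = brute_force_distance_to(vals, mask, 1, 7.5)
        np.testing.assert_array_equal(out.values[~mask], oracle[~mask])

    def test_nodata_cells_stay_nodata_and_are_not_targets(self):
        vals = np.zeros((4, 4), dtype=int)
        vals[0, 0] = 1
        vals[3, 3] = 1
        mask = np.zeros((4, 4), dtype=bool)
        mask[3, 3] = True  # the only other target is masked out
        out = distance_to(make_layer(vals, kind="categorical", mask=mask,
                                     cell_size=1.0), 1)
        assert out.nodata_mask[3, 3]
        # distance at (3,2) must refer to (0,0), not the masked (3,3)
        assert out.values[3, 2] == pytest.approx(np.sqrt(3 ** 2 + 2 ** 2))

    def test_absent_category_raises(self):
        with pytest.raises(ValueError, match="9"):
            distance_to(make_layer(np.zeros((3, 3), dtype=int), kind="categorical"), 9)


class TestCorrelation:
    @staticmethod
    def _stack_and_points(layers, n=50, seed=0):
        stack = EnvStack(layers)
        rng = np.random.default_rng(seed)
        nr, nc = stack.shape
        pts = pd.DataFrame(
            {"x": rng.uniform(0, nc * 10, n), "y": rng.uniform(0, nr * 10, n)}
        )
        return stack, pts

    def test_self_and_negation(self):
        rng = np.random.default_rng(2)
        vals = rng.random((10, 10))
        stack, pts = self._stack_and_points(
            [make_layer(vals, name="a"), make_layer(-vals, name="b")]
        )
        corr = pearson_correlation_matrix(stack, pts)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        stack, pts = self._stack_and_points(
            [make_layer(rng.random((10, 10)), name="a"),
             make_layer(rng.random((10, 10)), name="b")]
        )
        corr = pearson_correlation_matrix(stack, pts)
        tab = extract_values(stack, pts)
        a, b = tab["a"].to_numpy(), tab["b"].to_numpy()
        r = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert abs(corr.loc["a", "b"] - r) < 1e-12

    def test_independent_layers_nearly_uncorrelated(self):
        rng = np.random.default_rng(4)
        stack, pts = self._stack_and_points(
            [make_layer(rng.random((40, 40)), name="a"),
             make_layer(rng.random((40, 40)), name="b")],
            n=1000, seed=5,
        )
        corr = pearson_correlation_matrix(stack, pts)
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_zero_variance_layer_warns_and_reports_zero(self):
        rng = np.random.default_rng(5)
        stack, pts = self._stack_and_points(
            [make_layer(rng.random((10, 10)), name="a"),
             make_layer(np.full((10, 10), 3.0), name="flat")]
        )
        with pytest.warns(UserWarning, match="flat"):
            corr = pearson_correlation_matrix(stack, pts)
        assert corr.loc["a", "flat"] == 0.0
        assert corr.loc["flat", "flat"] == 1.0


class TestExtract:
    def test_cell_center_and_shared_cell(self, small_two_layer_stack):
        pts = pd.DataFrame({"x": [15.0, 12.0], "y": [25.0, 28.0]})  # same cell
        tab = extract_values(small_two_layer_stack, pts)
        assert tab.iloc[0]["gradient"] == tab.iloc[1]["gradient"]
        assert tab.iloc[0]["gradient"] == 11.0  # row 2, col 1

    def test_boundary_uses_half_open_convention(self, small_two_layer_stack):
        # x = 20 lies exactly on the boundary between col 1 and col 2
        pts = pd.DataFrame({"x": [20.0], "y": [5.0]})
        tab = extract_values(small_two_layer_stack, pts)
        row, col = int(5.0 // 10), int(20.0 // 10)  # index-arithmetic oracle
        assert tab.iloc[0]["gradient"] == small_two_layer_stack["gradient"].values[row, col]

    def test_outside_bbox_raises(self, small_two_layer_stack):
        with pytest.raises(ValueError, match="outside"):
            extract_values(small_two_layer_stack,
                           pd.DataFrame({"x": [55.0], "y": [5.0]}))

    def test_nodata_points_flagged(self):
        vals = np.arange(9, dtype=float).reshape(3, 3)
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = True
        stack = EnvStack([make_layer(vals, mask=mask)])
        tab = extract_values(stack, pd.DataFrame({"x": [5.0, 15.0], "y": [5.0, 15.0]}))
        assert not tab.iloc[0]["valid"]
        assert tab.iloc[1]["valid"]

    def test_all_points_on_nodata_raises(self):
        vals = np.zeros((2, 2))
        mask = np.ones((2, 2), dtype=bool)
        mask[1, 1] = False
        stack = EnvStack([make_layer(vals, mask=mask)])
        with pytest.raises(ValueError, match="nodata"):
            extract_values(stack, pd.DataFrame({"x": [5.0], "y": [5.0]}))
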