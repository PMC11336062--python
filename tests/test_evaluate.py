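"""Spatial folds, AUC, omission, Boyce index and null models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from vector_enm.evaluate import (
    auc,
    boyce_index,
    classify_auc,
    cross_validate,
    null_model_test,
    omission_rate,
    spatial_block_folds,
)
from vector_enm.model import ModelSettings
from vector_enm.reference import pairwise_auc


def _pts(xy):
    return pd.DataFrame(xy, columns=["x", "y"])


class TestFolds:
    def test_eight_distinct_points_two_per_fold(self):
        rng = np.random.default_rng(1)
        pres = _pts(rng.uniform(0, 100, size=(8, 2)))
        folds = spatial_block_folds(pres, pres.copy())
        counts = np.bincount(folds.presence_fold, minlength=5)[1:]
        assert sorted(counts.tolist()) == [2, 2, 2, 2]

    def test_square_corners_one_per_fold(self):
        pres = _pts([(0, 0), (0, 10), (10, 0), (10, 10)])
        folds = spatial_block_folds(pres, pres.copy())
        assert sorted(folds.presence_fold.tolist()) == [1, 2, 3, 4]

    def test_assignment_recomputable_from_split_lines(self):
        rng = np.random.default_rng(2)
        pres = _pts(rng.uniform(0, 1000, size=(37, 2)))
        bg = _pts(rng.uniform(0, 1000, size=(200, 2)))
        folds = spatial_block_folds(pres, bg)
        sl = folds.split_lines
        for tab, assigned in ((pres, folds.presence_fold), (bg, folds.background_fold)):
            left = tab["x"].to_numpy() < sl["x"]
            yline = np.where(left, sl["y_left"], sl["y_right"])
            low = tab["y"].to_numpy() < yline
            expect = np.where(left, np.where(low, 1, 2), np.where(low, 3, 4))
            np.testing.assert_array_equal(assigned, expect)

    def test_partition_and_balance(self):
        rng = np.random.default_rng(3)
        pres = _pts(rng.uniform(0, 50, size=(21, 2)))
        folds = spatial_block_folds(pres, pres.copy())
        counts = np.bincount(folds.presence_fold, minlength=5)[1:]
        assert counts.sum() == 21
        assert counts.max() - counts.min() <= 1

    def test_unsupported_k_and_too_few_points(self):
        pres = _pts([(0, 0), (1, 1), (2, 2), (3, 3)])
        with pytest.raises(ValueError, match="k=4"):
            spatial_block_folds(pres, pres, k=5)
        with pytest.raises(ValueError, match="4"):
            spatial_block_folds(pres.head(3), pres)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_identical_scores_half(self):
        assert auc([0.4, 0.4], [0.4, 0.4, 0.4]) == 0.5

    def test_example_equals_pair_enumeration(self):
        p, b = [0.9, 0.4], [0.5, 0.3, 0.2]
        assert auc(p, b) == pairwise_auc(p, b)

    @given(
        p=st.lists(st.integers(0, 10), min_size=1, max_size=20),
        b=st.lists(st.integers(0, 10), min_size=1, max_size=20),
    )
    @hyp_settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_pair_enumeration_with_ties(self, p, b):
        assert auc(p, b) == pairwise_auc(p, b)

    @given(
        scores=st.lists(st.floats(0.05, 1, allow_nan=False), min_size=8,
                        max_size=30, unique=True)
    )
    @hyp_settings(max_examples=40, derandomize=True, deadline=None)
    def test_invariance_and_complement(self, scores):
        half = len(scores) // 2
        p, b = scores[:half], scores[half:]
        base = auc(p, b)
        transformed = auc(np.exp(3 * np.asarray(p)), np.exp(3 * np.asarray(b)))
        assert transformed == pytest.approx(base)
        assert auc(p, b) + auc(b, p) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestBands:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.3, "random"),
            (0.5, "random"),
            (0.6, "poor to moderate"),
            (0.89, "moderate to high"),
            (0.7, "moderate to high"),
            (0.9, "excellent"),
            (0.95, "excellent"),
        ],
    )
    def test_band_edges(self, value, band):
        assert classify_auc(value) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_auc(1.2)


class TestOmission:
    def test_no_test_score_below_min(self):
        assert omission_rate([0.2, 0.5], [0.2, 0.9]) == 0.0

    def test_one_in_three_below(self):
        assert omission_rate([0.2, 0.5, 0.8], [0.1, 0.3, 0.9]) == pytest.approx(1 / 3)

    def test_p10_matches_percentile_oracle(self):
        rng = np.random.default_rng(4)
        train = rng.random(100)
        test = rng.random(40)
        got = omission_rate(train, test, rule="p10")
        tau = np.percentile(train, 10)
        assert got == np.mean(test < tau)

    def test_unknown_rule(self):
        with pytest.raises(ValueError, match="rule"):
            omission_rate([0.1], [0.1], rule="median")


class TestBoyce:
    def test_presences_proportional_to_score_high_index(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            b = rng.random(4000)
            p = rng.choice(b, size=300, p=b / b.sum())
            if boyce_index(p, b) >= 0.9:
                hits += 1
        assert hits >= 4

    def test_uniform_presences_centred_on_zero(self):
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(200 + seed)
            b = rng.random(2000)
            p = rng.choice(b, size=200)
            vals.append(boyce_index(p, b))
        assert abs(np.mean(vals)) < 0.15

    def test_inverted_alignment_negative(self):
        rng = np.random.default_rng(5)
        b = rng.random(4000)
        w = (1 - b)
        p = rng.choice(b, size=300, p=w / w.sum())
        assert boyce_index(p, b) < -0.5

    def test_degenerate_background_rejected(self):
        with pytest.raises(ValueError, match="range"):
            boyce_index([0.5], [0.3, 0.3])


class TestCrossValidate:
    @staticmethod
    def _data(seed=6, n_p=24, n_b=300):
        rng = np.random.default_rng(seed)
        pres = pd.DataFrame(
            {"x": rng.uniform(0, 100, n_p), "y": rng.uniform(0, 100, n_p),
             "v": rng.random(n_p) ** 2, "w": rng.random(n_p)}
        )
        bg = pd.DataFrame(
            {"x": rng.uniform(0, 100, n_b), "y": rng.uniform(0, 100, n_b),
             "v": rng.random(n_b), "w": rng.random(n_b)}
        )
        return pres, bg

    def test_bookkeeping_four_folds(self):
        pres, bg = self._data()
        folds = spatial_block_folds(pres, bg)
        kinds = {"v": "continuous", "w": "continuous"}
        cv = cross_validate(pres, bg, ["v", "w"], kinds,
                            ModelSettings(rm=1.0, fc="LQ"), folds)
        assert len(cv.fold_auc) == 4
        assert cv.mean_auc == pytest.approx(np.mean(cv.fold_auc))
        assert cv.mean_omission == pytest.approx(np.mean(cv.fold_omission))
        assert all(0 <= a <= 1 for a in cv.fold_auc)
        assert all(0 <= o <= 1 for o in cv.fold_omission)

    def test_uninformative_model_near_half_auc(self):
        # huge penalty forces zero weights -> constant scores -> AUC 0.5
        pres, bg = self._data(seed=7)
        folds = spatial_block_folds(pres, bg)
        kinds = {"v": "continuous", "w": "continuous"}
        settings = ModelSettings(rm=500.0, fc="L")
        cv = cross_validate(pres, bg, ["v", "w"], kinds, settings, folds)
        assert cv.mean_auc == pytest.approx(0.5)


class TestNullModel:
    @staticmethod
    def _background(seed=8, n=150):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"v": rng.random(n), "w": rng.random(n)})

    def test_observed_above_all_nulls(self):
        bg = self._background()
        kinds = {"v": "continuous", "w": "continuous"}
        res = null_model_test(1.0, bg, m=10, variables=["v", "w"], kinds=kinds,
                              settings=ModelSettings(fc="L"), n_null=25, seed=0)
        assert res.significant
        assert res.empirical_p == pytest.approx(1 / 26)

    def test_observed_below_median_not_significant(self):
        bg = self._background()
        kinds = {"v": "continuous", "w": "continuous"}
        res = null_model_test(0.0, bg, m=10, variables=["v", "w"], kinds=kinds,
                              settings=ModelSettings(fc="L"), n_null=25, seed=0)
        assert not res.significant
        assert res.empirical_p == 1.0

    def test_significance_monotone_in_observed_auc(self):
        bg = self._background(seed=9)
        kinds = {"v": "continuous", "w": "continuous"}
        flags = []
        for obs in (0.3, 0.5, 0.7, 0.9, 1.0):
            res = null_model_test(obs, bg, m=8, variables=["v", "w"], kinds=kinds,
                                  settings=ModelSettings(fc="L"), n_null=20, seed=3)
            flags.append(res.significant)
        assert flags == sorted(flags)  # once significant, stays significant

    def test_m_floor(self):
        bg = self._background()
        with pytest.raises(ValueError, match="m >= 4"):
            null_model_test(0.9, bg, m=3, variables=["v"],
                            kinds={"v": "continuous"},
                            settings=ModelSettings(fc="L"))
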