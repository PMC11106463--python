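"""Blocked CV, the two error metrics, importance and the scheme comparison."""

import numpy as np
import pandas as pd
import pytest

from geosmr.blocks import cluster_regions
from geosmr.errors import InvalidInputError
from geosmr.geostat import pairwise_distances
from geosmr.regression import (
    compare_cv_schemes,
    fit_full,
    fit_predict_cv,
    locv_folds,
    mae,
    permutation_importance_table,
    r2,
)
from geosmr.types import BlockAssignment


def assignment_from_labels(labels):
    labels = np.asarray(labels)
    return BlockAssignment(
        region_ids=np.arange(len(labels)),
        labels=labels,
        cut_distance=1.0,
        linkage_name="complete",
        n_blocks=int(labels.max()) + 1,
    )


class TestMetrics:
    def test_r2_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2(y, y) == pytest.approx(1.0)
        assert r2(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_r2_direct_evaluation(self):
        assert r2(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 2.0])) == pytest.approx(0.5)

    def test_r2_constant_y_rejected(self):
        with pytest.raises(InvalidInputError):
            r2(np.ones(5), np.arange(5.0))

    def test_mae_examples(self):
        y = np.array([1.0, 2.0, 3.0])
        assert mae(y, y) == 0.0
        assert mae(y, np.array([2.0, 2.0, 2.0])) == pytest.approx(2.0 / 3.0)

    def test_mae_shift_bound(self):
        rng = np.random.default_rng(0)
        y, y_hat = rng.random(20), rng.random(20)
        c = 0.37
        assert mae(y, y_hat + c) <= mae(y, y_hat) + c + 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_agreement_with_one_line_oracles(self, seed):
        rng = np.random.default_rng(seed)
        y, y_hat = rng.standard_normal(50), rng.standard_normal(50)
        r2_oracle = 1 - np.sum((y - y_hat) ** 2) / np.sum((y - y.mean()) ** 2)
        mae_oracle = np.abs(y - y_hat).mean()
        assert r2(y, y_hat) == pytest.approx(r2_oracle, abs=1e-12)
        assert mae(y, y_hat) == pytest.approx(mae_oracle, abs=1e-12)


class TestFolds:
    def test_two_blocks_complementary(self):
        folds = locv_folds(assignment_from_labels([0, 0, 1, 1]))
        assert len(folds) == 2
        assert sorted(folds[0][1].tolist() + folds[1][1].tolist()) == [0, 1, 2, 3]

    def test_validation_sets_partition_regions(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 6, size=40)
        labels[:6] = np.arange(6)  # every block non-empty
        folds = locv_folds(assignment_from_labels(labels))
        seen = np.concatenate([v for _, v in folds])
        assert sorted(seen.tolist()) == list(range(40))
        for train, val in folds:
            assert not set(train) & set(val)


class TestFitPredictCV:
    def _data(self, n=60, p=5, seed=0, signal=True):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=[f"f{i}" for i in range(p)],
                         index=pd.RangeIndex(n, name="region_id"))
        y = 2 * x["f0"].to_numpy() + 0.1 * rng.standard_normal(n) if signal \
            else rng.standard_normal(n)
        return x, y

    def test_constant_target_predicted_exactly(self):
        x, _ = self._data(n=20, seed=1)
        y = np.full(20, 3.0)
        labels = np.repeat(np.arange(4), 5)
        res = fit_predict_cv(x, y, locv_folds(assignment_from_labels(labels)),
                             {"n_estimators": 20}, seed=0)
        assert res.mae_pooled == pytest.approx(0.0, abs=1e-12)

    def test_informative_feature_gives_skill(self):
        x, y = self._data(n=120, seed=2)
        labels = np.repeat(np.arange(6), 20)
        res = fit_predict_cv(x, y, locv_folds(assignment_from_labels(labels)), {}, seed=0)
        assert res.r2_pooled > 0.5

    def test_determinism(self):
        x, y = self._data(n=40, seed=3)
        folds = locv_folds(assignment_from_labels(np.repeat(np.arange(4), 10)))
        r1 = fit_predict_cv(x, y, folds, {"n_estimators": 30}, seed=5)
        r2_ = fit_predict_cv(x, y, folds, {"n_estimators": 30}, seed=5)
        assert np.array_equal(r1.y_pred, r2_.y_pred)

    def test_out_of_fold_coverage(self):
        x, y = self._data(n=30, seed=4)
        folds = locv_folds(assignment_from_labels(np.repeat(np.arange(5), 6)))
        res = fit_predict_cv(x, y, folds, {"n_estimators": 10}, seed=0)
        assert np.all(np.isfinite(res.y_pred))
        assert np.all(res.fold_ids >= 0)

    def test_mismatched_target_rejected(self):
        x, y = self._data(n=10, seed=5)
        with pytest.raises(InvalidInputError):
            fit_predict_cv(x, y[:-1], [(np.arange(5), np.arange(5, 10))])


class TestPermutationImportance:
    def test_constant_feature_importance_zero(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"signal": rng.standard_normal(80), "const": np.ones(80)})
        y = x["signal"].to_numpy() * 2
        model = fit_full(x, y, {"n_estimators": 30}, seed=0)
        table = permutation_importance_table(model, x, y, n_repeats=5, seed=0)
        assert table.set_index("feature").loc["const", "importance_mean"] == 0.0

    def test_planted_signal_ranked_first(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.standard_normal((100, 5)), columns=list("abcde"))
        y = 3 * x["c"].to_numpy() + 0.1 * rng.standard_normal(100)
        model = fit_full(x, y, {}, seed=0)
        table = permutation_importance_table(model, x, y, n_repeats=10, seed=0)
        assert table.iloc[0]["feature"] == "c"


class TestCompareCVSchemes:
    def test_deterministic_gap(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.standard_normal((40, 4)))
        y = rng.standard_normal(40)
        a = assignment_from_labels(np.repeat(np.arange(4), 10))
        c1 = compare_cv_schemes(x, y, a, k_random=4, n_repeats=2, seed=9,
                                model_config={"n_estimators": 20})
        c2 = compare_cv_schemes(x, y, a, k_random=4, n_repeats=2, seed=9,
                                model_config={"n_estimators": 20})
        assert c1.gap == c2.gap
        assert c1.r2_random_repeats == c2.r2_random_repeats

    def test_iid_noise_gives_no_skill_either_way(self):
        # pure-noise target: both schemes near or below zero on average
        gaps, r2s = [], []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            x = pd.DataFrame(rng.standard_normal((60, 5)))
            y = rng.standard_normal(60)
            a = assignment_from_labels(np.repeat(np.arange(6), 10))
            c = compare_cv_schemes(x, y, a, k_random=6, n_repeats=1, seed=seed,
                                   model_config={"n_estimators": 50})
            gaps.append(c.gap)
            r2s.extend([c.r2_spatial, c.r2_random])
        assert np.mean(r2s) <= 0.1
        assert abs(np.mean(gaps)) < 0.4
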