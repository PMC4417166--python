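import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epibind.forest import ForestConfig
from epibind.modeling import (
    ConstantInputError,
    SingularDesignError,
    SplitSpec,
    coefficient_of_determination,
    feature_target_correlations,
    fit_bin_model,
    importance_ranks,
    pearson_cc,
    predict_affinity,
    repeated_cv,
    split_anchors,
)
from epibind.signal import BinFeatureMatrix


class TestSplit:
    def test_two_thirds_of_33292_is_22194(self):
        ids = [f"a{i}" for i in range(33_292)]
        train, test = split_anchors(ids, 2 / 3, np.random.default_rng(0))
        assert len(train) == 22_194 and len(test) == 33_292 - 22_194

    def test_minimal_split(self):
        train, test = split_anchors(["a", "b", "c"], 2 / 3, np.random.default_rng(1))
        assert len(train) == 2 and len(test) == 1

    def test_partition_properties(self, rng):
        ids = [f"a{i}" for i in range(257)]
        train, test = split_anchors(ids, 2 / 3, rng)
        assert set(train) | set(test) == set(ids)
        assert set(train) & set(test) == set()

    def test_reproducible_given_seed(self):
        ids = [f"a{i}" for i in range(100)]
        s1 = split_anchors(ids, 0.5, np.random.default_rng(7))
        s2 = split_anchors(ids, 0.5, np.random.default_rng(7))
        assert s1 == s2

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            split_anchors(["a", "b"], 0.5, np.random.default_rng(0))


class TestScores:
    def test_pearson_perfect_and_inverse(self):
        a = np.array([1.0, 2.0, 5.0])
        assert pearson_cc(a, a) == 1.0
        assert pearson_cc(a, -a) == -1.0

    def test_pearson_against_hand_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 7.0])
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        assert pearson_cc(a, b) == pytest.approx(expected, abs=1e-12)

    def test_pearson_constant_input_errors(self):
        with pytest.raises(ConstantInputError):
            pearson_cc([1, 1, 1], [1, 2, 3])

    def test_r2_modes_agree_on_perfect_fit(self):
        obs = np.array([1.0, 2.0, 4.0])
        assert coefficient_of_determination(obs, obs, "squared_pcc") == pytest.approx(1.0)
        assert coefficient_of_determination(obs, obs, "one_minus_ss") == pytest.approx(1.0)

    def test_r2_mean_prediction_is_zero_under_ss(self):
        obs = np.array([1.0, 2.0, 4.0])
        pred = np.full(3, obs.mean())
        assert coefficient_of_determination(obs, pred, "one_minus_ss") == pytest.approx(0.0)

    def test_r2_modes_diverge_on_anticorrelated_line(self):
        obs = np.array([1.0, 2.0, 4.0])
        assert coefficient_of_determination(obs, -obs, "squared_pcc") == pytest.approx(1.0)
        assert coefficient_of_determination(obs, -obs, "one_minus_ss") < 0


class TestFitPredict:
    def test_mlr_interpolates_exact_linear_target(self, rng):
        X = rng.normal(size=(50, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.7
        model = fit_bin_model(X, y, "mlr")
        assert np.allclose(predict_affinity(model, X), y, atol=1e-8)

    def test_singular_design_names_collinear_column(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 2] = X[:, 1]
        with pytest.raises(SingularDesignError, match="f[12]"):
            fit_bin_model(X, rng.normal(size=30), "mlr")

    def test_rf_constant_target_predicts_constant(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.full(40, 2.5)
        model = fit_bin_model(X, y, "rf", ForestConfig(n_trees=20), seed=1)
        assert np.allclose(predict_affinity(model, X), 2.5)

    def test_refit_same_seed_identical(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        p1 = predict_affinity(fit_bin_model(X, y, "rf", ForestConfig(n_trees=25), seed=3), X)
        p2 = predict_affinity(fit_bin_model(X, y, "rf", ForestConfig(n_trees=25), seed=3), X)
        assert np.array_equal(p1, p2)

    def test_predict_empty_and_mismatch(self, rng):
        X = rng.normal(size=(20, 3))
        model = fit_bin_model(X, X[:, 0], "mlr")
        assert predict_affinity(model, np.empty((0, 3))).size == 0
        with pytest.raises(ValueError, match="feature mismatch"):
            predict_affinity(model, rng.normal(size=(5, 4)))

    def test_prediction_row_order_equivariant(self, rng):
        X = rng.normal(size=(30, 3))
        model = fit_bin_model(X, X @ [1, 2, 3], "mlr")
        perm = rng.permutation(30)
        assert np.allclose(predict_affinity(model, X)[perm], predict_affinity(model, X[perm]))


def _matrix(X, y, bin_index=1):
    ids = [f"a{i}" for i in range(X.shape[0])]
    names = [f"f{j}" for j in range(X.shape[1])]
    return BinFeatureMatrix(bin_index, ids, names, X, y)


class TestRepeatedCV:
    def test_noiseless_linear_target_is_perfectly_predicted_by_mlr(self, rng):
        X = rng.normal(size=(90, 4))
        m = _matrix(X, X @ [1.0, 2.0, -1.0, 0.5])
        ev = repeated_cv(m, "mlr", SplitSpec(n_repeats=5, master_seed=11))
        assert ev.mean_pcc == pytest.approx(1.0, abs=1e-8)

    def test_permuted_labels_give_null_accuracy(self, rng):
        X = rng.normal(size=(300, 5))
        y = rng.permutation(X @ [1, 1, 1, 1, 1])  # break the X-y link
        ev = repeated_cv(_matrix(X, y), "mlr", SplitSpec(n_repeats=20, master_seed=5))
        assert abs(ev.mean_pcc) < 0.1

    def test_same_master_seed_reproduces_per_repeat_lists(self, rng):
        X = rng.normal(size=(60, 3))
        y = X[:, 0] + rng.normal(0, 0.5, 60)
        spec = SplitSpec(n_repeats=4, master_seed=2)
        e1 = repeated_cv(_matrix(X, y), "rf", spec, ForestConfig(n_trees=15))
        e2 = repeated_cv(_matrix(X, y), "rf", spec, ForestConfig(n_trees=15))
        assert e1.per_repeat_pcc == e2.per_repeat_pcc

    def test_constant_target_errors_after_skipping_all_repeats(self, rng):
        X = rng.normal(size=(30, 3))
        m = _matrix(X, np.zeros(30))
        with pytest.raises(RuntimeError, match="degenerate"):
            repeated_cv(m, "mlr", SplitSpec(n_repeats=5, master_seed=1))

    def test_mean_equals_mean_of_per_repeat_values(self, rng):
        X = rng.normal(size=(80, 3))
        y = X[:, 0] + rng.normal(0, 1, 80)
        ev = repeated_cv(_matrix(X, y), "mlr", SplitSpec(n_repeats=6, master_seed=9))
        assert ev.mean_pcc == pytest.approx(np.mean(ev.per_repeat_pcc))
        assert ev.mean_r2 == pytest.approx(np.mean(np.square(ev.per_repeat_pcc)))


class TestImportanceRanks:
    def test_example_ordering(self):
        ranks, ties = importance_ranks([5.2, 1.1, 9.0])
        assert ranks.tolist() == [2, 3, 1] and not ties

    def test_all_equal_scores_fall_back_to_feature_order(self):
        ranks, ties = importance_ranks([1.0] * 5)
        assert ranks.tolist() == [1, 2, 3, 4, 5] and ties

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=12))
    def test_ranks_are_a_permutation(self, scores):
        ranks, _ = importance_ranks(scores)
        assert sorted(ranks.tolist()) == list(range(1, len(scores) + 1))

    def test_twelve_features_span_one_to_twelve(self, rng):
        ranks, _ = importance_ranks(rng.normal(size=12))
        assert sorted(ranks.tolist()) == list(range(1, 13))


class TestFeatureTargetCorrelations:
    def test_copied_and_scaled_features(self, rng):
        X = rng.normal(size=(100, 3))
        m = _matrix(X, X[:, 1].copy())
        corr = feature_target_correlations(m)
        assert corr[1] == pytest.approx(1.0)
        m2 = _matrix(X, -2.0 * X[:, 2])
        assert feature_target_correlations(m2)[2] == pytest.approx(-1.0)

    def test_independent_feature_near_zero(self, rng):
        X = rng.normal(size=(500, 2))
        m = _matrix(X, rng.normal(size=500))
        assert np.all(np.abs(feature_target_correlations(m)) < 0.15)

    def test_constant_feature_is_nan(self, rng):
        X = rng.normal(size=(50, 2))
        X[:, 0] = 3.0
        corr = feature_target_correlations(_matrix(X, rng.normal(size=50)))
        assert np.isnan(corr[0]) and not np.isnan(corr[1])
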