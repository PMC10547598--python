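import numpy as np
import pytest
from sklearn import metrics as skmetrics

from _reference import oracle_classification_metrics, oracle_regression_metrics
from rootsense.data_io import SensoryRecord
from rootsense.errors import (
    ConfigurationError,
    EmptyInputError,
    InputError,
    UndefinedMetricError,
)
from rootsense.modelling import (
    MEALINESS_PRESETS,
    ErrorAnalysisRow,
    ModelConfig,
    SplitSpec,
    best_k,
    classification_metrics,
    cross_validate,
    error_analysis,
    label_policy,
    predict_scores,
    regression_metrics,
    save_model,
    load_model,
    split_dataset,
    train_classifier,
    train_nn_with_early_stopping,
    train_regressor,
    worst_k,
)


class TestSplitDataset:
    def test_reproduces_reference_counts(self):
        # 152 annotated items at (0.60, 0.25, 0.15) -> 91/38/23.
        parts = split_dataset(list(range(152)), SplitSpec((0.60, 0.25, 0.15), seed=0))
        assert [len(p) for p in parts] == [91, 38, 23]

    def test_80_20(self):
        parts = split_dataset(list(range(100)), SplitSpec((0.8, 0.2), seed=1))
        assert [len(p) for p in parts] == [80, 20]

    def test_deterministic(self):
        s = SplitSpec((0.7, 0.3), seed=77)
        assert split_dataset(list(range(50)), s) == split_dataset(list(range(50)), s)

    def test_disjoint_and_exhaustive(self):
        parts = split_dataset(list(range(37)), SplitSpec((0.5, 0.3, 0.2), seed=3))
        flat = [x for p in parts for x in p]
        assert sorted(flat) == list(range(37))

    def test_bad_fractions(self):
        with pytest.raises(ConfigurationError):
            SplitSpec((0.5, 0.6))

    def test_too_few_items(self):
        with pytest.raises(EmptyInputError):
            split_dataset([1], SplitSpec((0.5, 0.5)))


class TestRegressionMetrics:
    def test_perfect(self):
        y = np.array([1.0, 2.0, 3.0])
        assert regression_metrics(y, y) == (0.0, 0.0, 1.0)

    def test_hand_case(self):
        # Oracle: MAE = 1, MSE = 1, R2 = 1 - 2/50 = 0.96.
        mae, mse, r2 = regression_metrics([0, 10], [1, 9])
        assert (mae, mse, r2) == (1.0, 1.0, 0.96)

    def test_mean_prediction_r2_zero(self):
        y = np.array([2.0, 4.0, 6.0])
        _, _, r2 = regression_metrics(y, np.full(3, y.mean()))
        assert r2 == 0.0

    def test_matches_definitional_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 51))
            y = rng.normal(size=n)
            yhat = rng.normal(size=n)
            ours = regression_metrics(y, yhat)
            ref = oracle_regression_metrics(y, yhat)
            for a, b in zip(ours, ref):
                assert a == pytest.approx(b, abs=1e-12)

    def test_matches_sklearn(self, rng):
        y = rng.normal(size=30)
        yhat = rng.normal(size=30)
        mae, mse, r2 = regression_metrics(y, yhat)
        assert mae == pytest.approx(skmetrics.mean_absolute_error(y, yhat), abs=1e-12)
        assert mse == pytest.approx(skmetrics.mean_squared_error(y, yhat), abs=1e-12)
        assert r2 == pytest.approx(skmetrics.r2_score(y, yhat), abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            regression_metrics([3.0, 3.0], [1.0, 2.0])


class TestClassificationMetrics:
    def test_perfect(self):
        y = [0, 1, 3, 5, 8, 10]
        p, r, f1, _ = classification_metrics(y, y)
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_confusion_table_case(self):
        # Positive class (code 1): TP=3, FP=1, FN=2 ->
        # precision 0.75, recall 0.6, F1 = 2*.75*.6/1.35.
        y =    [1, 1, 1, 1, 1, 0, 0, 0, 0]
        yhat = [1, 1, 1, 0, 0, 1, 0, 0, 0]
        _, _, _, table = classification_metrics(y, yhat, classes=(0, 1))
        assert table[1]["precision"] == pytest.approx(0.75)
        assert table[1]["recall"] == pytest.approx(0.6)
        assert table[1]["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_all_one_class_precision_is_prevalence(self):
        y = [0, 0, 1, 1, 1, 0]
        yhat = [1] * 6
        _, _, _, table = classification_metrics(y, yhat, classes=(0, 1))
        assert table[1]["precision"] == pytest.approx(3 / 6)

    def test_matches_definitional_oracle_and_sklearn(self, rng):
        classes = (0, 1, 3, 5, 8, 10)
        for _ in range(10):
            n = int(rng.integers(5, 50))
            y = rng.choice(classes, size=n)
            yhat = rng.choice(classes, size=n)
            p, r, f1, table = classification_metrics(y, yhat)
            (rp, rr, rf1), rtable = oracle_classification_metrics(y, yhat, classes)
            assert (p, r, f1) == pytest.approx((rp, rr, rf1), abs=1e-12)
            present = sorted(set(y) | set(yhat))
            skp = skmetrics.precision_score(y, yhat, labels=present, average="macro", zero_division=0)
            skr = skmetrics.recall_score(y, yhat, labels=present, average="macro", zero_division=0)
            skf = skmetrics.f1_score(y, yhat, labels=present, average="macro", zero_division=0)
            assert (p, r, f1) == pytest.approx((skp, skr, skf), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            classification_metrics([], [])


class TestTrainRegressor:
    def test_linear_recovers_exact_fit(self, rng):
        X = rng.normal(size=(40, 3))
        beta = np.array([2.0, -1.0, 0.5])
        y = X @ beta + 4.0
        model = train_regressor(X, y, ModelConfig("linear"))
        assert model.estimator.coef_ == pytest.approx(beta, abs=1e-8)
        assert model.estimator.intercept_ == pytest.approx(4.0, abs=1e-8)
        _, _, r2 = regression_metrics(y, model.predict(X))
        assert r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("family", ["linear", "knn", "decision_tree", "random_forest"])
    def test_constant_target_constant_prediction(self, family, rng):
        X = rng.normal(size=(30, 4))
        y = np.full(30, 5.0)
        model = train_regressor(X, y, ModelConfig(family))
        assert np.allclose(model.predict(X), 5.0)

    def test_deterministic_predictions(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        for family in ("random_forest", "gradient_boosting", "decision_tree", "svm"):
            hyper = MEALINESS_PRESETS.get(family, {})
            m1 = train_regressor(X, y, ModelConfig(family, hyperparameters=hyper, seed=3))
            m2 = train_regressor(X, y, ModelConfig(family, hyperparameters=hyper, seed=3))
            assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(InputError):
            train_regressor(rng.normal(size=(10, 2)), rng.normal(size=9), ModelConfig("linear"))

    def test_non_finite_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(InputError):
            train_regressor(X, np.array([1.0, 2.0]), ModelConfig("linear"))

    def test_unknown_family(self):
        with pytest.raises(ConfigurationError):
            ModelConfig("boosted_stump")


class TestNeuralNetEarlyStopping:
    def test_constant_val_mae_stops_at_101(self, rng, monkeypatch):
        # Force a constant validation MAE by freezing the weights (lr = 0).
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        config = ModelConfig("neural_net", hyperparameters={"learning_rate": 0.0})
        _, log = train_nn_with_early_stopping(X, y, config)
        assert log["stopped_epoch"] == 101
        assert len(set(np.round(log["val_mae"], 12))) == 1

    def test_exact_min_delta_improvement_does_not_reset(self, monkeypatch):
        # Drive the validation MAE schedule directly: epoch 1 -> 1.0, then a
        # one-off drop of exactly 0.005 at epoch 50. Strict '>' means the
        # drop must NOT reset patience, so training still stops at 101.
        from rootsense import modelling as m

        # 0.995 is written as 1.0 - 0.005 so the schedule value is the same
        # double the stopping rule compares against.
        drop = 1.0 - 0.005
        schedule = [1.0] * 49 + [drop] * 1000
        calls = {"n": 0}

        def fake_step(self, X, y, state):
            return 0.0

        def fake_predict(self, Xs):
            mae = schedule[min(calls["n"], len(schedule) - 1)]
            calls["n"] += 1
            # produce predictions with that exact MAE vs the zero target
            return np.full(Xs.shape[0], mae)

        monkeypatch.setattr(m._NumpyMLP, "_step", fake_step)
        monkeypatch.setattr(m._NumpyMLP, "predict_standardized", fake_predict)
        # 40 samples -> 4 validation rows, so the val-MAE mean of identical
        # values is float-exact (division by a power of two).
        X = np.zeros((40, 2))
        y = np.zeros(40)
        _, log = train_nn_with_early_stopping(X, y, ModelConfig("neural_net"))
        assert log["stopped_epoch"] == 101

    def test_linear_data_val_mae_improves(self, rng):
        X = rng.normal(size=(100, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + 0.5
        config = ModelConfig(
            "neural_net", hyperparameters={"learning_rate": 1e-2, "max_epochs": 500}, seed=0
        )
        _, log = train_nn_with_early_stopping(X, y, config)
        assert min(log["val_mae"]) < log["val_mae"][0]

    def test_deterministic(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        cfg = ModelConfig("neural_net", hyperparameters={"max_epochs": 120}, seed=5)
        m1, _ = train_nn_with_early_stopping(X, y, cfg)
        m2, _ = train_nn_with_early_stopping(X, y, cfg)
        assert np.array_equal(m1.predict(X), m2.predict(X))


class TestCrossValidate:
    def test_fold_sizes(self, rng):
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=100)
        reports = cross_validate(X, y, ModelConfig("linear"), folds=5, seed=0)
        assert [r.n_test for r in reports] == [20] * 5

    def test_partition_property(self, rng):
        # every sample lands in exactly one validation fold
        n = 83
        order = np.random.default_rng(9).permutation(n)
        folds = np.array_split(order, 5)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(n))

    def test_too_many_folds(self, rng):
        with pytest.raises(InputError):
            cross_validate(rng.normal(size=(3, 2)), rng.normal(size=3), ModelConfig("linear"), folds=5)

    def test_fold_mean_r2_close_to_single_split(self, rng):
        # linear ground truth with noise: CV mean R2 within sampling noise
        X = rng.normal(size=(200, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.3, 200)
        reports = cross_validate(X, y, ModelConfig("linear"), folds=5, seed=1)
        cv_r2 = np.mean([r.r2 for r in reports])
        split = split_dataset(list(range(200)), SplitSpec((0.8, 0.2), seed=2))
        model = train_regressor(X[split[0]], y[split[0]], ModelConfig("linear"))
        _, _, single_r2 = regression_metrics(y[split[1]], model.predict(X[split[1]]))
        assert abs(cv_r2 - single_r2) < 0.1


class TestErrorAnalysis:
    TRUTHS = [
        SensoryRecord("C_P_UGP20170334-27 R3", 0.400, 5.0, 100.0),
        SensoryRecord("BEAUREGARD", 2.0, 6.376, 100.0),
        SensoryRecord("EXACT", 4.0, 4.0, 100.0),
    ]

    def test_worked_flesh_colour_row(self):
        # Predicted 0.886 vs truth 0.400 -> absolute error 0.486.
        rows = error_analysis([("C_P_UGP20170334-27 R3", 0.886)], self.TRUTHS, "flesh_colour")
        assert rows[0].absolute_error == pytest.approx(0.486)

    def test_worked_mealiness_outlier_row(self):
        # Predicted 0.727 vs truth 6.376 -> absolute error 5.649.
        rows = error_analysis([("BEAUREGARD", 0.727)], self.TRUTHS, "mealiness")
        assert rows[0].absolute_error == pytest.approx(5.649)

    def test_exact_prediction_ranked_first(self):
        rows = error_analysis(
            [("BEAUREGARD", 1.0), ("EXACT", 4.0)], self.TRUTHS, "flesh_colour"
        )
        assert rows[0].variety_name == "EXACT"
        assert rows[0].absolute_error == 0.0

    def test_best_and_worst_helpers(self):
        rows = [
            ErrorAnalysisRow("a", 1.0, 1.1),
            ErrorAnalysisRow("b", 1.0, 3.0),
            ErrorAnalysisRow("c", 1.0, 1.0),
        ]
        assert [r.variety_name for r in best_k(rows, 2)] == ["c", "a"]
        assert [r.variety_name for r in worst_k(rows, 1)] == ["b"]

    def test_unknown_variety(self):
        with pytest.raises(InputError, match="NOPE"):
            error_analysis([("NOPE", 1.0)], self.TRUTHS)


class TestLabelPolicy:
    def test_mode_simple(self):
        assert label_policy([8, 8, 5], task="classification") == 8

    def test_mode_tie_lower(self):
        assert label_policy([5, 8], task="classification") == 5

    def test_mean(self):
        assert label_policy([7, 9], task="regression") == 8.0

    def test_empty(self):
        with pytest.raises(EmptyInputError):
            label_policy([])


class TestPredictScores:
    def test_unlimited_tree_memorizes_training_rows(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.uniform(0, 10, 30)
        model = train_regressor(X, y, ModelConfig("decision_tree"))
        assert predict_scores(model, X) == pytest.approx(y)

    def test_outputs_clipped(self, rng):
        X = np.linspace(0, 1, 20)[:, None]
        y = np.linspace(-5, 15, 20)
        model = train_regressor(X, y, ModelConfig("linear"))
        preds = predict_scores(model, X)
        assert preds.min() >= 0.0 and preds.max() <= 10.0

    def test_clip_disabled_for_positive_force(self, rng):
        X = np.linspace(0, 1, 20)[:, None]
        y = np.linspace(1000, 9000, 20)
        model = train_regressor(X, y, ModelConfig("linear"))
        preds = predict_scores(model, X, clip=None)
        assert preds.max() > 10.0

    def test_schema_mismatch_names_columns(self, rng):
        X = rng.normal(size=(10, 2))
        model = train_regressor(X, rng.normal(size=10), ModelConfig("linear"), ["a", "b"])
        with pytest.raises(InputError, match="schema"):
            predict_scores(model, X, feature_names=["a", "c"])

    def test_classifier_snaps_to_scale(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.choice([0, 1, 3, 5, 8, 10], size=40)
        model = train_classifier(X, y, ModelConfig("random_forest", task="classification"))
        preds = predict_scores(model, X)
        assert set(preds) <= {0.0, 1.0, 3.0, 5.0, 8.0, 10.0}


class TestModelSerialization:
    def test_round_trip_with_metadata(self, tmp_path, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = train_regressor(X, y, ModelConfig("random_forest", seed=2), ["a", "b", "c"])
        path = tmp_path / "model.pkl"
        save_model(model, path)
        loaded = load_model(path)
        assert np.array_equal(loaded.predict(X), model.predict(X))
        assert loaded.feature_names == ["a", "b", "c"]
        import json

        meta = json.loads((tmp_path / "model.pkl.json").read_text())
        assert meta["family"] == "random_forest"
        assert meta["feature_names"] == ["a", "b", "c"]
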