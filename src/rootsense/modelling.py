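"""Model training, cross-validation, evaluation and error analysis.

Regression families: linear, k-nearest-neighbours, decision tree, RBF
support vector machine, random forest, gradient boosting, and a small
custom neural network trained with early stopping on validation MAE.
Classification (decision tree / random forest) predicts the discrete
flesh-colour class codes.

Default hyperparameters follow the reference training setups; the two
random-forest presets differ by target (colour: 100 estimators, unlimited
depth, one feature per split; mealiness: 20 estimators, depth 8).
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from sklearn.ensemble import (
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .data_io import SensoryRecord
from .errors import (
    ConfigurationError,
    EmptyInputError,
    InputError,
    TrainingError,
    UndefinedMetricError,
)
from .features_colour import nearest_scale_class

__all__ = [
    "ModelConfig",
    "SplitSpec",
    "EvaluationReport",
    "ErrorAnalysisRow",
    "TrainedModel",
    "REGRESSION_FAMILIES",
    "DEFAULT_HYPERPARAMETERS",
    "MEALINESS_PRESETS",
    "split_dataset",
    "train_regressor",
    "train_classifier",
    "train_nn_with_early_stopping",
    "cross_validate",
    "regression_metrics",
    "classification_metrics",
    "error_analysis",
    "best_k",
    "worst_k",
    "label_policy",
    "predict_scores",
    "save_model",
    "load_model",
]

SCALE_CLASSES = (0, 1, 3, 5, 8, 10)

REGRESSION_FAMILIES = (
    "linear", "knn", "decision_tree", "svm",
    "random_forest", "gradient_boosting", "neural_net",
)
CLASSIFICATION_FAMILIES = ("decision_tree", "random_forest")

# Reference flesh-colour training setups (regression task).
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "linear": {"fit_intercept": True},
    "knn": {"n_neighbors": 5, "weights": "uniform", "metric": "minkowski"},
    "decision_tree": {
        "criterion": "squared_error", "splitter": "best",
        "max_depth": None, "min_samples_split": 2,
    },
    "svm": {"C": 1.0, "kernel": "rbf", "degree": 3, "gamma": "scale"},
    "random_forest": {
        "n_estimators": 100, "criterion": "squared_error",
        "max_depth": None, "min_samples_leaf": 1, "max_features": 1,
    },
    "gradient_boosting": {"learning_rate": 0.1, "max_depth": 8, "n_estimators": 200},
    "neural_net": {
        "hidden_layers": (64, 32, 16), "learning_rate": 1e-4,
        "max_epochs": 5000, "patience": 100, "min_delta": 0.005,
        "validation_fraction": 0.1,
    },
}

# Reference mealiness-target overrides.
MEALINESS_PRESETS: dict[str, dict[str, Any]] = {
    "random_forest": {"n_estimators": 20, "max_depth": 8, "max_features": 1.0},
    "gradient_boosting": {"learning_rate": 0.1, "max_depth": 8, "n_estimators": 200},
}


@dataclass(frozen=True)
class ModelConfig:
    family: str
    task: str = "regression"
    hyperparameters: dict[str, Any] = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ConfigurationError(f"unknown task {self.task!r}")
        families = REGRESSION_FAMILIES if self.task == "regression" else CLASSIFICATION_FAMILIES
        if self.family not in families:
            raise ConfigurationError(
                f"unknown {self.task} family {self.family!r}; choose from {families}"
            )

    def resolved_hyperparameters(self) -> dict[str, Any]:
        params = dict(DEFAULT_HYPERPARAMETERS.get(self.family, {}))
        params.update(self.hyperparameters)
        return params


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < f < 1 for f in self.fractions):
            raise ConfigurationError(f"fractions must lie in (0,1): {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError(f"fractions must sum to 1: {self.fractions}")


@dataclass
class EvaluationReport:
    n_test: int
    mae: float | None = None
    mse: float | None = None
    r2: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    per_class: dict[int, dict[str, float]] | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class ErrorAnalysisRow:
    variety_name: str
    predicted: float
    ground_truth: float

    @property
    def absolute_error(self) -> float:
        return abs(self.predicted - self.ground_truth)


@dataclass
class TrainedModel:
    estimator: Any
    config: ModelConfig
    feature_names: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float)))


def split_dataset(items: Sequence, spec: SplitSpec) -> list[list]:
    """Seeded shuffle then floor allocation; remainder goes to the last part.

    152 items at fractions (0.60, 0.25, 0.15) yield parts of 91/38/23.
    """
    items = list(items)
    n = len(items)
    if n < len(spec.fractions):
        raise EmptyInputError(f"{n} items cannot fill {len(spec.fractions)} parts")
    order = np.random.default_rng(spec.seed).permutation(n)
    sizes = [int(np.floor(f * n)) for f in spec.fractions[:-1]]
    sizes.append(n - sum(sizes))
    parts: list[list] = []
    offset = 0
    for size in sizes:
        parts.append([items[i] for i in order[offset : offset + size]])
        offset += size
    return parts


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise InputError(f"X must be 2-D, got {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise InputError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if X.shape[0] == 0:
        raise EmptyInputError("no training samples")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise InputError("non-finite values in features or targets")
    return X, y


def _build_regressor(config: ModelConfig) -> Any:
    p = config.resolved_hyperparameters()
    if config.family == "linear":
        return LinearRegression(fit_intercept=p["fit_intercept"])
    if config.family == "knn":
        return KNeighborsRegressor(
            n_neighbors=p["n_neighbors"], weights=p["weights"], metric=p["metric"]
        )
    if config.family == "decision_tree":
        return DecisionTreeRegressor(
            criterion=p["criterion"], splitter=p["splitter"], max_depth=p["max_depth"],
            min_samples_split=p["min_samples_split"], random_state=config.seed,
        )
    if config.family == "svm":
        return SVR(C=p["C"], kernel=p["kernel"], degree=p["degree"], gamma=p["gamma"])
    if config.family == "random_forest":
        return RandomForestRegressor(
            n_estimators=p["n_estimators"], criterion=p["criterion"],
            max_depth=p["max_depth"], min_samples_leaf=p["min_samples_leaf"],
            max_features=p["max_features"], random_state=config.seed,
        )
    if config.family == "gradient_boosting":
        return GradientBoostingRegressor(
            learning_rate=p["learning_rate"], max_depth=p["max_depth"],
            n_estimators=p["n_estimators"], random_state=config.seed,
        )
    raise ConfigurationError(f"no regressor builder for {config.family!r}")


def train_regressor(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """Fit one regression family; deterministic for a fixed config seed."""
    X, y = _check_xy(X, y)
    if config.task != "regression":
        raise ConfigurationError("train_regressor requires a regression config")
    if config.family == "neural_net":
        model, _ = train_nn_with_early_stopping(X, y, config, feature_names)
        return model
    est = _build_regressor(config).fit(X, y)
    return TrainedModel(est, config, feature_names or _default_names(X.shape[1]))


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """Fit a decision-tree or random-forest classifier on class codes."""
    X, y = _check_xy(X, y)
    if config.task != "classification":
        raise ConfigurationError("train_classifier requires a classification config")
    p = config.resolved_hyperparameters()
    if config.family == "decision_tree":
        est = DecisionTreeClassifier(
            max_depth=p.get("max_depth"), min_samples_split=p.get("min_samples_split", 2),
            random_state=config.seed,
        )
    else:
        est = RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100), max_depth=p.get("max_depth"),
            random_state=config.seed,
        )
    est.fit(X, y.astype(int))
    return TrainedModel(est, config, feature_names or _default_names(X.shape[1]))


def _default_names(d: int) -> list[str]:
    return [f"f{i}" for i in range(d)]


class _NumpyMLP:
    """Small fully connected network: input -> 64 -> 32 -> 16 -> 1, ReLU.

    Full-batch Adam on MSE loss.  Features and target are standardized
    internally (the default learning rate of 1e-4 assumes comparable
    scales); predictions are returned on the original target scale.
    """

    def __init__(self, hidden: tuple[int, ...], lr: float, seed: int) -> None:
        self.hidden = tuple(hidden)
        self.lr = lr
        self.seed = seed
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []

    def _init(self, d: int) -> None:
        rng = np.random.default_rng(self.seed)
        sizes = [d, *self.hidden, 1]
        self.weights = [
            rng.normal(0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(s) for s in sizes[1:]]

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [X]
        a = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = z if i == len(self.weights) - 1 else np.maximum(z, 0.0)
            acts.append(a)
        return a[:, 0], acts

    def _step(self, X: np.ndarray, y: np.ndarray, state: dict) -> float:
        pred, acts = self._forward(X)
        err = pred - y
        loss = float(np.mean(err**2))
        grad = (2.0 / len(y)) * err[:, None]
        grads_w, grads_b = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            a_in = acts[i]
            grads_w.append(a_in.T @ grad)
            grads_b.append(grad.sum(axis=0))
            if i > 0:
                grad = (grad @ self.weights[i].T) * (acts[i] > 0)
        grads_w.reverse()
        grads_b.reverse()
        # Adam update
        state["t"] += 1
        t = state["t"]
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (gw, gb) in enumerate(zip(grads_w, grads_b)):
            for key, g, param in (("w", gw, self.weights), ("b", gb, self.biases)):
                m = state[f"m{key}"][i] = b1 * state[f"m{key}"][i] + (1 - b1) * g
                v = state[f"v{key}"][i] = b2 * state[f"v{key}"][i] + (1 - b2) * g**2
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                param[i] -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        max_epochs: int,
        patience: int,
        min_delta: float,
        validation_fraction: float,
    ) -> dict:
        rng = np.random.default_rng(self.seed)
        n = len(y)
        n_val = max(1, int(round(validation_fraction * n)))
        if n - n_val < 1:
            raise InputError(f"{n} samples too few for a {validation_fraction:.0%} validation split")
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]

        self.x_mean = X.mean(axis=0)
        self.x_sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.y_mean = float(y.mean())
        self.y_sd = float(y.std()) or 1.0
        Xs = (X - self.x_mean) / self.x_sd
        ys = (y - self.y_mean) / self.y_sd

        self._init(X.shape[1])
        state = {
            "t": 0,
            "mw": [np.zeros_like(w) for w in self.weights],
            "vw": [np.zeros_like(w) for w in self.weights],
            "mb": [np.zeros_like(b) for b in self.biases],
            "vb": [np.zeros_like(b) for b in self.biases],
        }
        best_mae = np.inf
        best_params = None
        since_improvement = 0
        log: dict = {"val_mae": [], "stopped_epoch": None}
        for epoch in range(1, max_epochs + 1):
            loss = self._step(Xs[train_idx], ys[train_idx], state)
            if not np.isfinite(loss):
                raise TrainingError(f"training loss diverged at epoch {epoch}")
            val_pred = self.predict_standardized(Xs[val_idx])
            val_mae = float(np.mean(np.abs(val_pred - y[val_idx])))
            log["val_mae"].append(val_mae)
            if val_mae < best_mae - min_delta:  # strict: exactly min_delta does not count
                best_mae = val_mae
                best_params = ([w.copy() for w in self.weights], [b.copy() for b in self.biases])
                since_improvement = 0
            else:
                since_improvement += 1
            if since_improvement >= patience:
                log["stopped_epoch"] = epoch
                break
        else:
            log["stopped_epoch"] = max_epochs
        if best_params is not None:
            self.weights, self.biases = best_params
        log["best_val_mae"] = best_mae if np.isfinite(best_mae) else log["val_mae"][0]
        return log

    def predict_standardized(self, Xs: np.ndarray) -> np.ndarray:
        pred, _ = self._forward(Xs)
        return pred * self.y_sd + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        return self.predict_standardized(Xs)


def train_nn_with_early_stopping(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | None = None,
    feature_names: list[str] | None = None,
) -> tuple[TrainedModel, dict]:
    """Train the custom network; returns (model, training log).

    The train set is split 90/10 into training/validation; training halts
    at ``max_epochs`` or once the best validation MAE has not improved by
    strictly more than ``min_delta`` for ``patience`` consecutive epochs
    (constant validation MAE from epoch 1 therefore stops at epoch
    ``patience + 1``).  The log records per-epoch validation MAE and the
    stopping epoch; weights revert to the best-validation epoch.
    """
    config = config or ModelConfig("neural_net")
    X, y = _check_xy(X, y)
    p = config.resolved_hyperparameters()
    net = _NumpyMLP(tuple(p["hidden_layers"]), p["learning_rate"], config.seed)
    log = net.fit(
        X, y,
        max_epochs=p["max_epochs"], patience=p["patience"],
        min_delta=p["min_delta"], validation_fraction=p["validation_fraction"],
    )
    model = TrainedModel(net, config, feature_names or _default_names(X.shape[1]))
    return model, log


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    """(MAE, MSE, R^2) by the textbook definitions."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise InputError(f"bad metric input shapes: {y.shape} vs {yhat.shape}")
    err = yhat - y
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedMetricError("R^2 undefined: zero variance in y")
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return mae, mse, r2


def classification_metrics(
    y: Sequence[int],
    yhat: Sequence[int],
    classes: Sequence[int] = SCALE_CLASSES,
) -> tuple[float, float, float, dict[int, dict[str, float]]]:
    """Macro precision/recall/F1 plus the per-class one-vs-rest table.

    Classes absent from both ``y`` and ``yhat`` are excluded from the macro
    averages.  Per-class precision (recall) is defined as 0 when the class
    is never predicted (never present).
    """
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if y.size == 0 or y.shape != yhat.shape:
        raise InputError("empty or mismatched label vectors")
    bad = set(np.unique(y)) | set(np.unique(yhat))
    if not bad <= set(classes):
        raise InputError(f"labels {sorted(bad - set(classes))} outside class set {classes}")
    per_class: dict[int, dict[str, float]] = {}
    for cls in classes:
        if cls not in y and cls not in yhat:
            continue
        tp = int(np.sum((yhat == cls) & (y == cls)))
        fp = int(np.sum((yhat == cls) & (y != cls)))
        fn = int(np.sum((yhat != cls) & (y == cls)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[cls] = {"precision": precision, "recall": recall, "f1": f1}
    macro = {
        k: float(np.mean([v[k] for v in per_class.values()]))
        for k in ("precision", "recall", "f1")
    }
    return macro["precision"], macro["recall"], macro["f1"], per_class


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    folds: int = 5,
    seed: int = 0,
) -> list[EvaluationReport]:
    """Seeded shuffled K-fold cross-validation; one report per fold."""
    X, y = _check_xy(X, y)
    n = len(y)
    if folds > n:
        raise InputError(f"{folds} folds exceed {n} samples")
    order = np.random.default_rng(seed).permutation(n)
    reports = []
    for val_idx in np.array_split(order, folds):
        train_idx = np.setdiff1d(order, val_idx, assume_unique=True)
        model = train_regressor(X[train_idx], y[train_idx], config)
        yhat = model.predict(X[val_idx])
        mae, mse, r2 = regression_metrics(y[val_idx], yhat)
        reports.append(EvaluationReport(n_test=len(val_idx), mae=mae, mse=mse, r2=r2))
    return reports


def error_analysis(
    predictions: Sequence[tuple[str, float]],
    truths: Sequence[SensoryRecord],
    attribute: str = "flesh_colour",
) -> list[ErrorAnalysisRow]:
    """Absolute error per variety, sorted ascending (best first)."""
    field_map = {
        "flesh_colour": "flesh_colour_mean",
        "mealiness": "mealiness_by_hand_mean",
        "positive_force": "positive_force_1r",
    }
    if attribute not in field_map:
        raise ConfigurationError(f"unknown attribute {attribute!r}")
    by_variety = {t.variety_name: t for t in truths}
    rows = []
    for variety, predicted in predictions:
        if variety not in by_variety:
            raise InputError(f"variety {variety!r} not found in ground truth")
        truth = getattr(by_variety[variety], field_map[attribute])
        rows.append(ErrorAnalysisRow(variety, float(predicted), float(truth)))
    return sorted(rows, key=lambda r: r.absolute_error)


def best_k(rows: Sequence[ErrorAnalysisRow], k: int = 3) -> list[ErrorAnalysisRow]:
    return sorted(rows, key=lambda r: r.absolute_error)[:k]


def worst_k(rows: Sequence[ErrorAnalysisRow], k: int = 3) -> list[ErrorAnalysisRow]:
    return sorted(rows, key=lambda r: r.absolute_error, reverse=True)[:k]


def label_policy(panel_scores: Sequence[float], task: str = "regression") -> float | int:
    """Panel scores -> training target.

    Regression: arithmetic mean.  Classification: mode of the scores, ties
    broken toward the lower value.
    """
    scores = list(panel_scores)
    if not scores:
        raise EmptyInputError("no panel scores")
    if task == "regression":
        return float(np.mean(scores))
    if task == "classification":
        values, counts = np.unique(scores, return_counts=True)  # ascending values
        return int(values[np.argmax(counts)])  # argmax takes the first (lowest) on ties
    raise ConfigurationError(f"unknown task {task!r}")


def predict_scores(
    model: TrainedModel,
    X: np.ndarray,
    feature_names: list[str] | None = None,
    clip: tuple[float, float] | None = (0.0, 10.0),
) -> np.ndarray:
    """Predict with schema validation and range clipping.

    Classification models additionally snap outputs to the nearest scale
    class code.  Pass ``clip=None`` for the positive-force target.
    """
    X = np.asarray(X, dtype=float)
    if feature_names is not None and feature_names != model.feature_names:
        diverging = [
            f"{a!r}!={b!r}" for a, b in zip(feature_names, model.feature_names) if a != b
        ] + [f"count {len(feature_names)} vs {len(model.feature_names)}"] * (
            len(feature_names) != len(model.feature_names)
        )
        raise InputError(f"feature schema mismatch: {', '.join(diverging)}")
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise InputError(
            f"expected {len(model.feature_names)} features, got {X.shape}"
        )
    preds = model.predict(X).astype(float)
    if clip is not None:
        preds = np.clip(preds, *clip)
    if model.config.task == "classification":
        preds = np.array([nearest_scale_class(p) for p in preds], dtype=float)
    return preds


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a model with a JSON metadata sidecar (<path>.json)."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh)
    meta = {
        "schema_version": 1,
        "family": model.config.family,
        "task": model.config.task,
        "seed": model.config.seed,
        "hyperparameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.config.resolved_hyperparameters().items()
        },
        "feature_names": model.feature_names,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, TrainedModel):
        raise InputError(f"{path} does not contain a TrainedModel")
    return model
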