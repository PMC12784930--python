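"""Regressor contract for the daily body-weight and interval total-feed
models, evaluation metrics, an impurity-reduction verification utility,
and Monte-Carlo permutation Shapley attribution.

Learner internals are delegated to scikit-learn; this module owns the
uniform training/prediction/serialization contract, the named presets,
and the attribution estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.neural_network import MLPRegressor

from fowlplan.preprocessing import TransformState, apply_transform

logger = logging.getLogger(__name__)

__all__ = [
    "RegressorConfig",
    "PRESETS",
    "ModelHandle",
    "ModelMetrics",
    "AttributionSummary",
    "train_regressor",
    "evaluate",
    "impurity_reduction",
    "mc_shapley",
    "save_model",
    "load_model",
]

_ARTIFACT_VERSION = 1

FAMILIES = ("random-forest", "extra-trees", "gradient-boosting", "feedforward-net")


@dataclass(frozen=True)
class RegressorConfig:
    """Configuration of one regressor family.

    Only the fields relevant to ``family`` are used; the rest are ignored
    by construction of the underlying estimator.
    """

    family: str = "extra-trees"
    n_trees: int = 300
    max_depth: int | None = 6
    min_samples_split: int = 2
    learning_rate: float = 0.05
    hidden_widths: tuple[int, ...] = (64, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.family != "feedforward-net" and self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")


#: Named hyperparameter presets for the model comparison.
PRESETS: dict[str, RegressorConfig] = {
    "rf": RegressorConfig(family="random-forest", n_trees=300, max_depth=6, min_samples_split=5),
    "xgb": RegressorConfig(family="gradient-boosting", n_trees=600, max_depth=6, learning_rate=0.05),
    "et": RegressorConfig(family="extra-trees", n_trees=300, max_depth=6, min_samples_split=2),
    "ann": RegressorConfig(family="feedforward-net", hidden_widths=(64, 32)),
}


def _make_estimator(config: RegressorConfig):
    if config.family == "random-forest":
        return RandomForestRegressor(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            min_samples_split=config.min_samples_split,
            random_state=config.seed,
        )
    if config.family == "extra-trees":
        return ExtraTreesRegressor(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            min_samples_split=config.min_samples_split,
            random_state=config.seed,
        )
    if config.family == "gradient-boosting":
        return GradientBoostingRegressor(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            learning_rate=config.learning_rate,
            random_state=config.seed,
        )
    # feedforward net: ReLU hidden layers, Adam, L2 penalty, early stopping
    return MLPRegressor(
        hidden_layer_sizes=config.hidden_widths,
        activation="relu",
        solver="adam",
        learning_rate_init=0.001,
        alpha=0.001,
        max_iter=2000,
        tol=1e-4,
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=20,
        random_state=config.seed,
    )


@dataclass
class ModelHandle:
    """A fitted regressor plus the config and feature names it was trained
    with. ``predict`` accepts a 2-D array or feature-named DataFrame.

    When a ``transform`` is attached the handle expects *raw* feature
    values and scales them with the stored training statistics before
    delegating to the estimator.
    """

    estimator: object
    config: RegressorConfig
    feature_names: list[str] = field(default_factory=list)
    transform: TransformState | None = None
    scaling_method: str = "minmax"

    def predict(self, X) -> np.ndarray:
        if self.transform is not None:
            df = X if hasattr(X, "loc") else pd.DataFrame(
                _as_matrix(X, None), columns=self.feature_names
            )
            X = apply_transform(df[self.feature_names], self.transform, self.scaling_method)
        X = _as_matrix(X, self.feature_names)
        return np.asarray(self.estimator.predict(X), dtype=float)


def _as_matrix(X, feature_names: list[str] | None = None) -> np.ndarray:
    if hasattr(X, "loc") and feature_names:
        X = X[feature_names]
    arr = np.asarray(X, dtype=float)
    return arr.reshape(1, -1) if arr.ndim == 1 else arr


def train_regressor(
    config: RegressorConfig,
    X,
    y,
    feature_names: list[str] | None = None,
    transform: TransformState | None = None,
    scaling_method: str = "minmax",
) -> ModelHandle:
    """Fit a regressor of the configured family; deterministic given seed.

    If ``transform`` is given, ``X`` is taken as raw feature values and is
    scaled with the (train-fitted) state before fitting; the returned
    handle then scales inputs automatically on ``predict``.
    """
    if feature_names is None and hasattr(X, "columns"):
        feature_names = list(X.columns)
    if transform is not None:
        df = X if hasattr(X, "loc") else pd.DataFrame(
            np.asarray(X, dtype=float), columns=feature_names
        )
        X = apply_transform(df[feature_names], transform, scaling_method)
    X = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if X.shape[0] < 2:
        raise ValueError("at least 2 training rows required")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in training data after preprocessing")
    est = _make_estimator(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence warnings at small n
        est.fit(X, y)
    return ModelHandle(
        est,
        config,
        feature_names or [f"x{j}" for j in range(X.shape[1])],
        transform,
        scaling_method,
    )


def save_model(handle: ModelHandle, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": _ARTIFACT_VERSION,
            "config": asdict(handle.config),
            "feature_names": handle.feature_names,
            "estimator": handle.estimator,
            "transform": handle.transform,
            "scaling_method": handle.scaling_method,
        },
        path,
    )


def load_model(path: str | Path) -> ModelHandle:
    blob = joblib.load(path)
    if blob.get("format_version") != _ARTIFACT_VERSION:
        raise ValueError(f"unsupported model artifact version: {blob.get('format_version')}")
    cfg_dict = dict(blob["config"])
    cfg_dict["hidden_widths"] = tuple(cfg_dict["hidden_widths"])
    return ModelHandle(
        blob["estimator"],
        RegressorConfig(**cfg_dict),
        blob["feature_names"],
        blob.get("transform"),
        blob.get("scaling_method", "minmax"),
    )


@dataclass(frozen=True)
class ModelMetrics:
    """Regression accuracy summary; ``r2`` is NaN for zero-variance truth."""

    mse: float
    mae: float
    rmse: float
    r2: float


def evaluate(predictions, observations) -> ModelMetrics:
    """MSE, MAE, RMSE and R^2 = 1 - SS_res/SS_tot of predictions."""
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size < 2:
        raise ValueError("at least 2 observations required")
    resid = obs - pred
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        logger.warning("zero variance in observations; R^2 undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return ModelMetrics(mse=mse, mae=mae, rmse=float(np.sqrt(mse)), r2=r2)


def impurity_reduction(parent, children) -> float:
    """Variance impurity reduction of a candidate split.

    ``dI = I(D) - sum(|D_i|/|D| * I(D_i))`` with ``I`` the within-node
    variance. The children must partition the parent (as a multiset).
    """
    parent = np.asarray(parent, dtype=float)
    children = [np.asarray(c, dtype=float) for c in children]
    if sum(len(c) for c in children) != len(parent) or not np.array_equal(
        np.sort(parent), np.sort(np.concatenate(children) if children else np.array([]))
    ):
        raise ValueError("children do not partition the parent responses")
    n = len(parent)
    i_parent = float(np.var(parent))
    i_children = sum(len(c) / n * float(np.var(c)) for c in children if len(c))
    return i_parent - i_children


@dataclass(frozen=True)
class AttributionSummary:
    """Per-feature attribution summary, ranked by mean |Shapley value|."""

    feature_names: list[str]
    mean_abs: np.ndarray
    iqr: np.ndarray
    per_sample: np.ndarray  # (n_explain, p) signed Shapley estimates

    def ranking(self) -> list[tuple[str, float, float]]:
        order = np.argsort(-self.mean_abs)
        return [(self.feature_names[j], float(self.mean_abs[j]), float(self.iqr[j])) for j in order]


def mc_shapley(
    model,
    X_background,
    X_explain,
    n_permutations: int = 100,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> AttributionSummary:
    """Monte-Carlo permutation Shapley values with marginal replacement.

    For each explained row, features are inserted in random order into a
    background row drawn from ``X_background``; each feature's
    contribution is the change in model output when its value switches
    from the background's to the explained row's. Averaging over
    permutations estimates the Shapley value. The summary reports per
    feature the mean |value| and the interquartile range of |value|
    across explained samples.
    """
    if feature_names is None and hasattr(X_explain, "columns"):
        feature_names = list(X_explain.columns)
    predict = model.predict if hasattr(model, "predict") else model
    bg = _as_matrix(X_background, feature_names)
    Xe = _as_matrix(X_explain, feature_names)
    if bg.shape[0] == 0:
        raise ValueError("background set is empty")
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    n, p = Xe.shape
    names = feature_names or [f"x{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, p))
    for i in range(n):
        x = Xe[i]
        # one (permutation, background draw) pair per MC iteration;
        # rows of the walk matrix go from pure background to pure x
        contrib = np.zeros(p)
        for _ in range(n_permutations):
            order = rng.permutation(p)
            z = bg[rng.integers(bg.shape[0])].copy()
            walk = np.empty((p + 1, p))
            walk[0] = z
            for step, j in enumerate(order, start=1):
                z = z.copy()
                z[j] = x[j]
                walk[step] = z
            preds = np.asarray(predict(walk), dtype=float)
            contrib[order] += np.diff(preds)
        phi[i] = contrib / n_permutations
    abs_phi = np.abs(phi)
    q75, q25 = np.percentile(abs_phi, [75, 25], axis=0)
    return AttributionSummary(
        feature_names=names,
        mean_abs=abs_phi.mean(axis=0),
        iqr=q75 - q25,
        per_sample=phi,
    )
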