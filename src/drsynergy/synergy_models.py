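"""Classical regressor panel for synergy-score prediction.

Wraps LASSO (with an internal CV penalty grid), AdaBoost, Random Forest and
XGBoost behind one train/predict surface with seeded determinism and strict
feature-schema checks. Hyperparameter defaults are fixed here and logged
verbatim into the fitted state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.linear_model import LassoCV
from xgboost import XGBRegressor

from .errors import SchemaError, ValidationError
from .feature_assembly import PairDataset

ALGORITHMS = ("lasso", "adaboost", "rf", "xgb")

SERIALIZATION_VERSION = 1

DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "lasso": {"cv": 5, "alphas": 50, "max_iter": 5000},
    "adaboost": {"n_estimators": 100, "learning_rate": 1.0},
    "rf": {"n_estimators": 200, "min_samples_leaf": 2, "n_jobs": 1},
    "xgb": {
        "n_estimators": 200,
        "max_depth": 4,
        "learning_rate": 0.1,
        "tree_method": "hist",
        "n_jobs": 1,
        "verbosity": 0,
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice + hyperparameter overrides + seed."""

    algorithm: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )

    def resolved_hyperparameters(self) -> dict[str, Any]:
        return {**DEFAULT_HYPERPARAMETERS[self.algorithm], **self.hyperparameters}


@dataclass
class FittedModel:
    """Opaque fitted estimator plus the spec and feature schema it was trained with."""

    estimator: Any = field(repr=False)
    spec: ModelSpec = field(default_factory=lambda: ModelSpec("lasso"))
    feature_names: list[str] = field(default_factory=list)


def make_estimator(spec: ModelSpec):
    params = spec.resolved_hyperparameters()
    if spec.algorithm == "lasso":
        return LassoCV(random_state=spec.seed, **params)
    if spec.algorithm == "adaboost":
        return AdaBoostRegressor(random_state=spec.seed, **params)
    if spec.algorithm == "rf":
        return RandomForestRegressor(random_state=spec.seed, **params)
    return XGBRegressor(random_state=spec.seed, **params)


def train(dataset: PairDataset, spec: ModelSpec) -> FittedModel:
    """Fit one regressor on a pair dataset; deterministic given (dataset, spec)."""
    if dataset.n_rows == 0:
        raise ValidationError("cannot train on an empty dataset")
    X = dataset.X.to_numpy(dtype=float)
    y = dataset.y.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValidationError("non-finite features or targets in training data")
    if np.ptp(y) == 0:
        warnings.warn(
            f"constant target ({y[0]:g}); model will predict the constant", stacklevel=2
        )
        estimator = DummyRegressor(strategy="constant", constant=float(y[0])).fit(X, y)
    else:
        estimator = make_estimator(spec).fit(X, y)
    return FittedModel(estimator=estimator, spec=spec, feature_names=dataset.feature_names)


def predict(model: FittedModel, dataset: PairDataset) -> np.ndarray:
    """One finite score per row, in row order; rejects mismatched feature schemas."""
    if dataset.feature_names != model.feature_names:
        extra = sorted(set(dataset.feature_names) - set(model.feature_names))
        missing = sorted(set(model.feature_names) - set(dataset.feature_names))
        detail = f"extra={extra[:5]}, missing={missing[:5]}" if extra or missing else "column order differs"
        raise SchemaError(f"feature schema does not match training ({detail})")
    scores = np.asarray(model.estimator.predict(dataset.X.to_numpy(dtype=float)), dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("model produced non-finite predictions")
    return scores


def save_model(model: FittedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "serialization_version": SERIALIZATION_VERSION,
            "spec": model.spec,
            "feature_names": model.feature_names,
            "estimator": model.estimator,
        },
        path,
    )


def load_model(path: str | Path) -> FittedModel:
    payload = joblib.load(path)
    if payload.get("serialization_version") != SERIALIZATION_VERSION:
        raise ValidationError(f"unsupported model file version in {path}")
    return FittedModel(
        estimator=payload["estimator"],
        spec=payload["spec"],
        feature_names=payload["feature_names"],
    )
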