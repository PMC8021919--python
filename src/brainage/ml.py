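"""Conventional ML brain-age baselines: ridge and RBF-kernel SVR under nested
10-fold cross-validation.

The inner loop grid-searches the regularization hyperparameters by mean
negative MAE; the outer loop scores out-of-fold predictions, so every subject
is predicted exactly once by a model that never saw it.  Features are z-scored
inside each training split (SVR with an RBF kernel is scale-sensitive, and the
gamma grid only makes sense on standardized inputs); the scaler is part of the
fitted pipeline, so no statistic leaks across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .features import FeatureTable

Algorithm = Literal["ridge", "svr_rbf"]

RIDGE_LAMBDA_GRID = (0.001, 0.01, 1.0, 10.0, 100.0)
SVR_C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
SVR_GAMMA_GRID = SVR_C_GRID


@dataclass
class CVConfig:
    """Nested-CV layout and hyperparameter grids."""

    k_outer: int = 10
    k_inner: int = 10
    ridge_lambda_grid: tuple[float, ...] = RIDGE_LAMBDA_GRID
    svr_C_grid: tuple[float, ...] = SVR_C_GRID
    svr_gamma_grid: tuple[float, ...] = SVR_GAMMA_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("fold counts must be at least 2")
        for grid in (self.ridge_lambda_grid, self.svr_C_grid, self.svr_gamma_grid):
            if len(grid) == 0:
                raise ValueError("hyperparameter grids must be non-empty")


@dataclass
class CVResult:
    """Outcome of one nested-CV run."""

    algorithm: str
    fold_params: list[dict]
    predictions: np.ndarray  # out-of-fold predicted age per subject
    mae: float
    rmse: float
    r2: float

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "fold_params": self.fold_params,
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
        }


def _param_grid(algorithm: Algorithm, config: CVConfig) -> dict:
    if algorithm == "ridge":
        return {"model__alpha": list(config.ridge_lambda_grid)}
    if algorithm == "svr_rbf":
        return {
            "model__C": list(config.svr_C_grid),
            "model__gamma": list(config.svr_gamma_grid),
        }
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _pipeline(algorithm: Algorithm) -> Pipeline:
    if algorithm == "ridge":
        model = Ridge()
    elif algorithm == "svr_rbf":
        model = SVR(kernel="rbf")  # epsilon stays at its conventional default
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return Pipeline([("scale", StandardScaler()), ("model", model)])


def _inner_search(
    algorithm: Algorithm, config: CVConfig, seed: int
) -> GridSearchCV:
    return GridSearchCV(
        _pipeline(algorithm),
        _param_grid(algorithm, config),
        scoring="neg_mean_absolute_error",
        cv=KFold(n_splits=config.k_inner, shuffle=True, random_state=seed),
        n_jobs=None,
    )


def nested_cv(
    features: FeatureTable,
    ages: np.ndarray,
    algorithm: Algorithm,
    config: CVConfig | None = None,
) -> CVResult:
    """Nested k-fold CV: inner grid search per outer fold, pooled OOF metrics."""
    config = config or CVConfig()
    X = features.matrix
    y = np.asarray(ages, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("ages length must match feature rows")
    if X.shape[0] < 2 * config.k_outer:
        raise ValueError("too few subjects for the outer fold count")
    outer = KFold(n_splits=config.k_outer, shuffle=True, random_state=config.seed)
    predictions = np.full(len(y), np.nan)
    fold_params: list[dict] = []
    for fold, (tr, te) in enumerate(outer.split(X)):
        if np.ptp(y[te]) == 0:
            raise ValueError(f"outer fold {fold} has constant age; R^2 undefined")
        search = _inner_search(algorithm, config, seed=config.seed + fold + 1)
        search.fit(X[tr], y[tr])
        predictions[te] = search.predict(X[te])
        fold_params.append(dict(search.best_params_))
    assert not np.any(np.isnan(predictions))
    return CVResult(
        algorithm=algorithm,
        fold_params=fold_params,
        predictions=predictions,
        mae=float(mean_absolute_error(y, predictions)),
        rmse=float(np.sqrt(mean_squared_error(y, predictions))),
        r2=float(r2_score(y, predictions)),
    )


class BrainAgeEstimator:
    """A fitted pipeline plus its feature-name schema.

    Prediction aligns incoming tables to the training schema by column name,
    so column order does not matter; missing columns are an error.
    """

    def __init__(self, pipeline: Pipeline, feature_names: list[str], params: dict):
        self.pipeline = pipeline
        self.feature_names = list(feature_names)
        self.params = params

    def predict(self, features: FeatureTable) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.feature_names]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        frame = features.to_frame()[self.feature_names]
        return self.pipeline.predict(frame.to_numpy(dtype=float))


def fit_final(
    features: FeatureTable,
    ages: np.ndarray,
    algorithm: Algorithm,
    config: CVConfig | None = None,
) -> BrainAgeEstimator:
    """Select hyperparameters by inner CV on all rows, then refit on all rows."""
    config = config or CVConfig()
    y = np.asarray(ages, dtype=float)
    search = _inner_search(algorithm, config, seed=config.seed)
    search.fit(features.matrix, y)
    return BrainAgeEstimator(
        pipeline=search.best_estimator_,
        feature_names=features.feature_names,
        params=dict(search.best_params_),
    )
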