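"""Nested-CV ridge/SVR baselines: recovery, null behavior, leakage, schema."""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

from brainage.features import FeatureTable
from brainage.ml import (
    CVConfig,
    BrainAgeEstimator,
    fit_final,
    nested_cv,
)


def _linear_cohort(rng, n=300, p=20, noise_sd=2.0):
    X = rng.normal(size=(n, p))
    w = rng.normal(size=p)
    ages = 50.0 + X @ w * 3.0 + rng.normal(0, noise_sd, n)
    table = FeatureTable(
        matrix=X,
        feature_names=[f"f{i}" for i in range(p)],
        subject_ids=[f"s{i}" for i in range(n)],
    )
    return table, ages


def _null_mae(ages, k_outer, seed):
    """Mean-age predictor evaluated on the same outer folds."""
    from sklearn.model_selection import KFold

    preds = np.empty_like(ages)
    for tr, te in KFold(k_outer, shuffle=True, random_state=seed).split(ages):
        preds[te] = ages[tr].mean()
    return np.mean(np.abs(preds - ages))


class TestNestedCV:
    def test_ridge_beats_null_on_linear_cohort(self, rng):
        table, ages = _linear_cohort(rng)
        cfg = CVConfig(seed=0)
        result = nested_cv(table, ages, "ridge", cfg)
        null = _null_mae(ages, cfg.k_outer, cfg.seed)
        assert result.mae < 0.5 * null
        assert len(result.fold_params) == 10
        assert result.predictions.shape == (300,)

    def test_pure_noise_r2_near_zero(self, rng):
        table, _ = _linear_cohort(rng, n=200)
        ages = rng.uniform(17, 90, 200)  # independent of the features
        result = nested_cv(table, ages, "ridge", CVConfig(seed=1))
        assert result.r2 <= 0.05

    def test_seed_determinism(self, rng):
        table, ages = _linear_cohort(rng, n=120, p=5)
        a = nested_cv(table, ages, "ridge", CVConfig(seed=4))
        b = nested_cv(table, ages, "ridge", CVConfig(seed=4))
        assert np.array_equal(a.predictions, b.predictions)
        assert a.fold_params == b.fold_params

    def test_svr_runs_and_every_subject_predicted_once(self, rng):
        table, ages = _linear_cohort(rng, n=60, p=4)
        result = nested_cv(table, ages, "svr_rbf", CVConfig(seed=2))
        assert np.all(np.isfinite(result.predictions))
        assert result.mae >= 0

    def test_too_few_subjects(self, rng):
        table, ages = _linear_cohort(rng, n=15, p=3)
        with pytest.raises(ValueError):
            nested_cv(table, ages, "ridge", CVConfig(seed=0))


class TestFitFinal:
    def test_exact_model_recovery(self, rng):
        """Noise-free affine target: ridge at the smallest grid lambda gets
        holdout MAE well under 0.1 years."""
        X = rng.normal(size=(240, 10))
        w = rng.normal(size=10)
        ages = 40.0 + X @ w * 2.0
        table = FeatureTable(
            matrix=X[:200],
            feature_names=[f"f{i}" for i in range(10)],
            subject_ids=[f"s{i}" for i in range(200)],
        )
        est = fit_final(table, ages[:200], "ridge", CVConfig(seed=0))
        holdout = FeatureTable(
            matrix=X[200:],
            feature_names=table.feature_names,
            subject_ids=[f"h{i}" for i in range(40)],
        )
        pred = est.predict(holdout)
        assert np.mean(np.abs(pred - ages[200:])) < 0.1

    def test_schema_alignment_by_name(self, rng):
        table, ages = _linear_cohort(rng, n=80, p=4)
        est = fit_final(table, ages, "ridge", CVConfig(seed=0))
        base = est.predict(table)
        permuted = FeatureTable(
            matrix=table.matrix[:, ::-1],
            feature_names=table.feature_names[::-1],
            subject_ids=table.subject_ids,
        )
        assert np.allclose(est.predict(permuted), base)

    def test_missing_column_rejected(self, rng):
        table, ages = _linear_cohort(rng, n=80, p=4)
        est = fit_final(table, ages, "ridge", CVConfig(seed=0))
        partial = FeatureTable(
            matrix=table.matrix[:, :3],
            feature_names=table.feature_names[:3],
            subject_ids=table.subject_ids,
        )
        with pytest.raises(ValueError, match="f3"):
            est.predict(partial)


def test_small_lambda_ridge_approaches_ols(rng):
    """On an exactly-linear noise-free problem the standardized ridge fit at
    lambda = 0.001 is within 1e-3 of the OLS coefficients."""
    X = rng.normal(size=(150, 6))
    y = X @ rng.normal(size=6) * 2.0 + 30.0
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.linear_model import Ridge

    pipe = Pipeline([("s", StandardScaler()), ("m", Ridge(alpha=0.001))]).fit(X, y)
    ols = Pipeline([("s", StandardScaler()), ("m", LinearRegression())]).fit(X, y)
    assert np.max(np.abs(pipe["m"].coef_ - ols["m"].coef_)) < 1e-3


def test_standardization_within_training_split_only(rng):
    """The fitted scaler's statistics equal those recomputed from the training
    rows alone (no leakage from validation rows)."""
    table, ages = _linear_cohort(rng, n=100, p=5)
    est = fit_final(table, ages, "ridge", CVConfig(seed=0))
    scaler = est.pipeline["scale"]
    assert np.allclose(scaler.mean_, table.matrix.mean(axis=0))
    # refit on half the data: statistics track that half only
    half = FeatureTable(
        matrix=table.matrix[:50],
        feature_names=table.feature_names,
        subject_ids=table.subject_ids[:50],
    )
    est2 = fit_final(half, ages[:50], "ridge", CVConfig(seed=0))
    assert np.allclose(est2.pipeline["scale"].mean_, table.matrix[:50].mean(axis=0))
    assert not np.allclose(est2.pipeline["scale"].mean_, scaler.mean_)
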