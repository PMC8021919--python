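"""Prediction assessment and brain-age-delta bias correction.

The brain-age delta is predicted age minus chronological age.  Regression
estimators systematically overpredict young and underpredict old subjects
(regression toward the mean), which makes delta negatively correlated with
age; the correction here residualizes delta on age with an OLS line fitted on
training predictions (Cole-style), then shifts each prediction by the fitted
trend.

The metric report covers MAE, RMSE, R^2, the Spearman correlation of delta
with age (the bias criterion), and the Kullback-Leibler divergence between
the chronological and predicted age distributions, estimated on shared
histogram bins with additive smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

#: Default KLD binning: 5-year bins spanning the adult lifespan.
KLD_BIN_EDGES = np.arange(15.0, 95.0 + 5.0, 5.0)
KLD_SMOOTHING = 1e-6


@dataclass
class PredictionBatch:
    """Paired chronological (``y``) and predicted (``y_pred``) ages, in years."""

    y: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.y_pred = np.atleast_1d(np.asarray(self.y_pred, dtype=float))
        if self.y.shape != self.y_pred.shape:
            raise ValueError("y and y_pred must have equal length")
        if self.y.ndim != 1:
            raise ValueError("ages must be 1-D vectors")
        if self.y.size and not (
            np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.y_pred))
        ):
            raise ValueError("ages must be finite")

    @property
    def n(self) -> int:
        return int(self.y.size)


@dataclass
class BiasModel:
    """OLS fit of delta = a + b * age on a training batch."""

    intercept: float  # a, years
    slope: float  # b, dimensionless


@dataclass
class MetricReport:
    mae: float
    rmse: float
    r2: float
    rho: float  # Spearman correlation of delta with chronological age
    kld: float  # nats

    def to_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2,
                "rho": self.rho, "kld": self.kld}


def brain_age_delta(batch: PredictionBatch) -> np.ndarray:
    """Elementwise predicted minus chronological age."""
    return batch.y_pred - batch.y


def kl_divergence(p: np.ndarray, q: np.ndarray, smoothing: float = 0.0) -> float:
    """KL(P || Q) in nats for two discrete distributions on shared support."""
    p = np.asarray(p, dtype=float) + smoothing
    q = np.asarray(q, dtype=float) + smoothing
    p = p / p.sum()
    q = q / q.sum()
    support = p > 0
    if np.any(q[support] == 0):
        return float("inf")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def age_distribution_kld(
    y: np.ndarray,
    y_pred: np.ndarray,
    bin_edges: np.ndarray = KLD_BIN_EDGES,
    smoothing: float = KLD_SMOOTHING,
) -> float:
    """KLD between chronological (P) and predicted (Q) age histograms."""
    p, _ = np.histogram(y, bins=bin_edges)
    q, _ = np.histogram(y_pred, bins=bin_edges)
    return kl_divergence(p, q, smoothing=smoothing)


def metric_report(batch: PredictionBatch) -> MetricReport:
    """MAE/RMSE/R^2, Spearman(delta, age), and age-distribution KLD."""
    if batch.n < 3:
        raise ValueError("need at least 3 subjects for a metric report")
    y, yp = batch.y, batch.y_pred
    if np.ptp(y) == 0:
        raise ValueError("constant chronological ages: R^2 and rho undefined")
    delta = brain_age_delta(batch)
    if np.ptp(delta) == 0:
        rho = 0.0  # delta is constant (e.g., perfect prediction): no rank trend
    else:
        rho = float(stats.spearmanr(delta, y).statistic)
    return MetricReport(
        mae=float(mean_absolute_error(y, yp)),
        rmse=float(np.sqrt(mean_squared_error(y, yp))),
        r2=float(r2_score(y, yp)),
        rho=rho,
        kld=age_distribution_kld(y, yp),
    )


def plot_age_distributions(batch: PredictionBatch, path, bins=KLD_BIN_EDGES):
    """Overlapping histograms of chronological vs predicted age (KLD figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(batch.y, bins=bins, alpha=0.5, label="chronological age")
    ax.hist(batch.y_pred, bins=bins, alpha=0.5, label="predicted brain age")
    kld = age_distribution_kld(batch.y, batch.y_pred, bin_edges=np.asarray(bins))
    ax.set_xlabel("age (years)")
    ax.set_ylabel("subjects")
    ax.set_title(f"KLD = {kld:.4f} nats")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def fit_bias(train_batch: PredictionBatch) -> BiasModel:
    """Fit the age trend of delta on a training batch (OLS)."""
    if np.ptp(train_batch.y) == 0:
        raise ValueError("cannot fit a bias model on constant ages")
    delta = brain_age_delta(train_batch)
    slope, intercept = np.polyfit(train_batch.y, delta, 1)
    return BiasModel(intercept=float(intercept), slope=float(slope))


def apply_bias(model: BiasModel, batch: PredictionBatch) -> PredictionBatch:
    """Residualize delta on age: subtract the fitted trend from each delta."""
    delta = brain_age_delta(batch)
    corrected_delta = delta - (model.intercept + model.slope * batch.y)
    return PredictionBatch(y=batch.y, y_pred=batch.y + corrected_delta)
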