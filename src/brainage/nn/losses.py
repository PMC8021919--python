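"""Batch losses for the age regressor, with closed-form gradients.

Let Y be the chronological ages and Y' the predictions in a mini-batch of
size N, and E = Y' - Y the error vector.

* Covariance loss: the mean over rows of the squared entries of the outer
  product E (x) Y^T,

      L_cov = (1/N) * sum_ij (E_i * Y_j)^2 = ||E||^2 * ||Y||^2 / N.

  Penalizing this outer product discourages prediction error that co-varies
  with age (the regression-to-the-mean signature).

* Ranking loss: the mean over rows of the squared difference between the
  Gram (outer-product) matrices of predictions and of true ages,

      L_rank = (1/N) * sum_ij (Y'_i Y'_j - Y_i Y_j)^2,

  which preserves the pairwise ordering structure of ages within the batch.

The composite training loss is MAE in years, optionally plus one of these
regularizers scaled by ``reg_weight``.
"""

from __future__ import annotations

import numpy as np

from ..evaluation import PredictionBatch

LOSS_MODES = ("plain", "cov_reg", "rank_reg")


def _vectors(batch: PredictionBatch) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(batch.y, dtype=float)
    yp = np.asarray(batch.y_pred, dtype=float)
    if y.size == 0:
        raise ValueError("empty batch")
    return y, yp


def covariance_loss(batch: PredictionBatch) -> float:
    y, yp = _vectors(batch)
    e = yp - y
    return float(np.dot(e, e) * np.dot(y, y) / y.size)


def covariance_loss_grad(batch: PredictionBatch) -> np.ndarray:
    """d L_cov / d Y'."""
    y, yp = _vectors(batch)
    return 2.0 * (yp - y) * np.dot(y, y) / y.size


def ranking_loss(batch: PredictionBatch) -> float:
    y, yp = _vectors(batch)
    diff = np.outer(yp, yp) - np.outer(y, y)
    return float((diff**2).sum() / y.size)


def ranking_loss_grad(batch: PredictionBatch) -> np.ndarray:
    """d L_rank / d Y'_k = (4/N) * (Y'_k ||Y'||^2 - Y_k (Y . Y'))."""
    y, yp = _vectors(batch)
    return 4.0 / y.size * (yp * np.dot(yp, yp) - y * np.dot(y, yp))


def mae_loss(batch: PredictionBatch) -> float:
    y, yp = _vectors(batch)
    return float(np.mean(np.abs(yp - y)))


def mae_loss_grad(batch: PredictionBatch) -> np.ndarray:
    y, yp = _vectors(batch)
    return np.sign(yp - y) / y.size


def composite_loss(batch: PredictionBatch, mode: str, reg_weight: float = 1e-4) -> float:
    """MAE plus the selected regularizer scaled by ``reg_weight``."""
    if mode == "plain":
        return mae_loss(batch)
    if mode == "cov_reg":
        return mae_loss(batch) + reg_weight * covariance_loss(batch)
    if mode == "rank_reg":
        return mae_loss(batch) + reg_weight * ranking_loss(batch)
    raise ValueError(f"unknown loss mode {mode!r}; expected one of {LOSS_MODES}")


def composite_loss_grad(
    batch: PredictionBatch, mode: str, reg_weight: float = 1e-4
) -> np.ndarray:
    if mode == "plain":
        return mae_loss_grad(batch)
    if mode == "cov_reg":
        return mae_loss_grad(batch) + reg_weight * covariance_loss_grad(batch)
    if mode == "rank_reg":
        return mae_loss_grad(batch) + reg_weight * ranking_loss_grad(batch)
    raise ValueError(f"unknown loss mode {mode!r}; expected one of {LOSS_MODES}")
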