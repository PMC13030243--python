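"""Hybrid BCE + Dice segmentation objective.

total = BCE + (1 − soft Dice): binary cross-entropy drives per-pixel
fidelity while the soft Dice term rewards global region overlap; the
combination is the standard remedy for the foreground/background imbalance
of lesion masks. Gradients are derived in closed form for the numpy
training loop and are finite everywhere on (0, 1) predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BCE_EPS = 1e-7
DICE_EPS = 1e-5


@dataclass(frozen=True)
class LossValue:
    bce: float
    dice_term: float

    @property
    def total(self) -> float:
        return self.bce + (1.0 - self.dice_term)


def _check(pred: np.ndarray, target: np.ndarray):
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes must match")
    return pred, target


def bce_loss(pred: np.ndarray, target: np.ndarray, eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy; predictions clamped to [eps, 1-eps]."""
    pred, target = _check(pred, target)
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log1p(-p)))


def dice_soft(pred: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> float:
    """Soft Dice coefficient (2 Σ P·G + eps) / (Σ P + Σ G + eps)."""
    pred, target = _check(pred, target)
    return float(
        (2.0 * np.sum(pred * target) + eps)
        / (np.sum(pred) + np.sum(target) + eps)
    )


def combined_loss(pred: np.ndarray, target: np.ndarray) -> LossValue:
    """BCE plus Dice loss (1 − soft Dice) as a structured value."""
    return LossValue(bce=bce_loss(pred, target), dice_term=dice_soft(pred, target))


def combined_loss_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d(total)/d(pred): analytic gradient of the hybrid objective."""
    pred, target = _check(pred, target)
    n = pred.size
    p = np.clip(pred, BCE_EPS, 1.0 - BCE_EPS)
    dbce = (p - target) / (p * (1.0 - p)) / n
    s_pg = np.sum(pred * target)
    s_p, s_g = np.sum(pred), np.sum(target)
    denom = s_p + s_g + DICE_EPS
    ddice = (2.0 * target * denom - (2.0 * s_pg + DICE_EPS)) / denom**2
    return dbce - ddice
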