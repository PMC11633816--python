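"""Segmentation loss functions over SoftMax probability maps.

All losses are pure functions of a per-pixel class-probability array
(``pixels x classes`` after flattening any leading spatial axes) and a
one-hot ground truth of identical shape.  They share a single soft-confusion
kernel (probabilistic TP/FP/FN sums), which makes the family relationships
explicit and testable:

* Dice loss          : 1 - mean_c 2TP/(2TP+FP+FN)
* Jaccard loss       : 1 - mean_c TP/(TP+FP+FN),  J = D/(2-D) per class
* focal Tversky loss : mean_c (1 - TP/(TP + a*FP + b*FN))^gamma;
                       a = b = 0.5, gamma = 1 reduces to Dice
* F-beta ("recall-favored") loss: 1 - mean_c F_beta; beta = 1 reduces to
  Dice/F1, beta = 0 to precision, beta -> inf to recall
* combo loss         : w * categorical cross-entropy + (1 - w) * Dice loss

Soft (probabilistic) sums rather than hard argmax keep every loss
differentiable, which is what a gradient-trained segmenter needs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "LossParams",
    "soft_confusion",
    "dice_loss",
    "jaccard_loss",
    "focal_tversky_loss",
    "rf_loss",
    "combo_loss",
    "categorical_cross_entropy",
    "LOSS_REGISTRY",
    "get_loss",
]


@dataclasses.dataclass(frozen=True)
class LossParams:
    """Loss-family hyperparameters.

    beta            : F-beta asymmetry weight (recall weighting); >= 0.
    alpha_tversky   : Tversky false-positive weight.
    beta_tversky    : Tversky false-negative weight (alpha + beta = 1 by default).
    gamma           : focal exponent applied to (1 - Tversky index); > 0.
    w_cce           : cross-entropy weight of the combo loss; Dice weight is 1 - w_cce.
    epsilon         : additive smoothing constant protecting empty classes.
    """

    beta: float = 1.0
    alpha_tversky: float = 0.5
    beta_tversky: float = 0.5
    gamma: float = 1.0
    w_cce: float = 0.5
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not 0.0 <= self.w_cce <= 1.0:
            raise ValueError("w_cce must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _flatten(probs: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if probs.shape != truth.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs truth {truth.shape}")
    k = probs.shape[-1]
    return probs.reshape(-1, k), truth.reshape(-1, k)


def _soft_counts(probs: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class probabilistic (tp, fp, fn) sums, shape (classes,)."""
    p, t = _flatten(probs, truth)
    tp = np.sum(p * t, axis=0)
    fp = np.sum(p * (1.0 - t), axis=0)
    fn = np.sum((1.0 - p) * t, axis=0)
    return tp, fp, fn


def soft_confusion(probs: np.ndarray, truth: np.ndarray, class_id: int) -> tuple[float, float, float]:
    """Probabilistic (tp, fp, fn) for one class column.

    Satisfies ``tp + fn == true pixel count`` of the class exactly.
    """
    tp, fp, fn = _soft_counts(probs, truth)
    return float(tp[class_id]), float(fp[class_id]), float(fn[class_id])


def dice_loss(probs: np.ndarray, truth: np.ndarray, params: LossParams = LossParams()) -> float:
    """1 minus the class-mean soft Dice similarity coefficient."""
    tp, fp, fn = _soft_counts(probs, truth)
    e = params.epsilon
    dsc = (2.0 * tp + e) / (2.0 * tp + fp + fn + e)
    return float(1.0 - dsc.mean())


def jaccard_loss(probs: np.ndarray, truth: np.ndarray, params: LossParams = LossParams()) -> float:
    """1 minus the class-mean soft Jaccard index (IoU)."""
    tp, fp, fn = _soft_counts(probs, truth)
    e = params.epsilon
    jac = (tp + e) / (tp + fp + fn + e)
    return float(1.0 - jac.mean())


def focal_tversky_loss(probs: np.ndarray, truth: np.ndarray,
                       params: LossParams = LossParams()) -> float:
    """Class-mean (1 - Tversky index)^gamma.

    ``alpha_tversky`` penalizes false positives, ``beta_tversky`` false
    negatives; the focal exponent ``gamma`` damps the contribution of
    already-well-segmented classes.
    """
    tp, fp, fn = _soft_counts(probs, truth)
    e = params.epsilon
    ti = (tp + e) / (tp + params.alpha_tversky * fp + params.beta_tversky * fn + e)
    return float(np.mean((1.0 - ti) ** params.gamma))


def rf_loss(probs: np.ndarray, truth: np.ndarray, params: LossParams = LossParams()) -> float:
    """1 minus the class-mean soft F-beta score ("recall-favored" loss).

    ``beta`` trades recall against precision: beta = 1 is the harmonic mean
    (F1 = Dice), beta = 0 is precision, beta -> inf approaches recall.
    """
    if params.beta < 0:
        raise ValueError("beta must be >= 0")
    tp, fp, fn = _soft_counts(probs, truth)
    e = params.epsilon
    b2 = params.beta**2
    fbeta = ((1.0 + b2) * tp + e) / ((1.0 + b2) * tp + b2 * fn + fp + e)
    return float(1.0 - fbeta.mean())


def categorical_cross_entropy(probs: np.ndarray, truth: np.ndarray,
                              params: LossParams = LossParams()) -> float:
    """Pixel-mean cross-entropy of the SoftMax output against one-hot truth."""
    p, t = _flatten(probs, truth)
    return float(-np.mean(np.sum(t * np.log(p + params.epsilon), axis=1)))


def combo_loss(probs: np.ndarray, truth: np.ndarray,
               params: LossParams = LossParams()) -> float:
    """Convex mixture ``w_cce * CCE + (1 - w_cce) * Dice loss``."""
    w = params.w_cce
    return float(w * categorical_cross_entropy(probs, truth, params)
                 + (1.0 - w) * dice_loss(probs, truth, params))


#: name -> callable registry used by the grid-search module
LOSS_REGISTRY = {
    "Dice": dice_loss,
    "Jaccard": jaccard_loss,
    "FocalTversky": focal_tversky_loss,
    "RFLoss": rf_loss,
    "ComboLoss": combo_loss,
}


def get_loss(name: str):
    """Look up a loss by registry name."""
    try:
        return LOSS_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown loss {name!r}; available: {sorted(LOSS_REGISTRY)}"
        ) from None
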