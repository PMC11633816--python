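"""Hard-label evaluation metrics, per class and as background-aware means.

The suite mirrors what a segmentation study logs every epoch: overall pixel
accuracy, categorical accuracy, and per-class Dice, Jaccard, precision and
recall, each aggregated twice — once over all classes including background
and once over foreground classes only.  Logging both variants matters in
background-dominated images: a model that predicts background everywhere
scores high mean precision *including* background while its foreground-only
precision is undefined (it declares no positives at all), which is exactly
the conservative-model pathology the dual means are designed to expose.

Undefined 0/0 cells (e.g. precision with no declared positives) are reported
as NaN and excluded from means by default; a strict mode scores them 0
instead.  Silent zeros would hide the pathology rather than reveal it.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["ConfusionTally", "MetricReport", "tally", "metric_report", "epoch_suite",
           "metric_schema"]


@dataclasses.dataclass(frozen=True)
class ConfusionTally:
    """Per-class one-vs-rest TP/FP/FN/TN pixel counts."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_classes: int
    total_pixels: int

    def __post_init__(self) -> None:
        for arr in (self.tp, self.fp, self.fn, self.tn):
            if np.any(arr < 0):
                raise ValueError("confusion counts must be non-negative")
        sums = self.tp + self.fp + self.fn + self.tn
        if np.any(sums != self.total_pixels):
            raise ValueError("tp+fp+fn+tn must equal total_pixels for every class")


def tally(pred_labels: np.ndarray, true_labels: np.ndarray, n_classes: int) -> ConfusionTally:
    """One-vs-rest confusion counts from hard label maps."""
    pred = np.asarray(pred_labels).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.shape != true.shape:
        raise ValueError("pred and true label shapes differ")
    if pred.size and (pred.max() >= n_classes or true.max() >= n_classes
                      or pred.min() < 0 or true.min() < 0):
        raise ValueError("labels out of range for n_classes")
    # bincount-based confusion matrix; much faster than sklearn's checked path
    cm = np.bincount(true * n_classes + pred,
                     minlength=n_classes * n_classes).reshape(n_classes, n_classes)
    tp = np.diag(cm).astype(np.int64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    total = int(cm.sum())
    tn = total - tp - fp - fn
    return ConfusionTally(tp=tp, fp=fp, fn=fn, tn=tn, n_classes=n_classes,
                          total_pixels=total)


@dataclasses.dataclass
class MetricReport:
    """Per-class metrics plus both mean variants; NaN marks undefined cells."""

    per_class: dict[str, np.ndarray]
    accuracy: float
    means: dict[str, float]
    n_classes: int


def _safe_div(num: np.ndarray, den: np.ndarray, strict: bool) -> np.ndarray:
    out = np.full(num.shape, np.nan, dtype=np.float64)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if strict:
        out = np.nan_to_num(out, nan=0.0)
    return out


def _nanmean(values: np.ndarray, strict: bool) -> float:
    if strict:
        return float(np.mean(values))
    if np.all(np.isnan(values)):
        return float("nan")
    return float(np.nanmean(values))


def metric_report(t: ConfusionTally, strict: bool = False) -> MetricReport:
    """Compute the metric suite from a confusion tally.

    With ``strict=False`` (default) 0/0 cells are NaN and dropped from means;
    with ``strict=True`` they score 0.
    """
    tp, fp, fn = t.tp.astype(float), t.fp.astype(float), t.fn.astype(float)
    per_class = {
        "precision": _safe_div(tp, tp + fp, strict),
        "recall": _safe_div(tp, tp + fn, strict),
        "dice": _safe_div(2 * tp, 2 * tp + fp + fn, strict),
        "jaccard": _safe_div(tp, tp + fp + fn, strict),
    }
    accuracy = float(tp.sum() / t.total_pixels) if t.total_pixels else float("nan")
    means: dict[str, float] = {}
    for name, vals in per_class.items():
        means[f"{name}_mean_bg"] = _nanmean(vals, strict)
        means[f"{name}_mean_nobg"] = _nanmean(vals[1:], strict)
    return MetricReport(per_class=per_class, accuracy=accuracy, means=means,
                        n_classes=t.n_classes)


def metric_schema(n_classes: int, losses_to_log: list[str] | None = None) -> list[str]:
    """The exact, versioned metric-name vocabulary emitted by epoch_suite."""
    names = ["accuracy", "categorical_accuracy"]
    for m in ("dice", "jaccard", "precision", "recall"):
        names += [f"{m}_c{c}" for c in range(n_classes)]
        names += [f"{m}_mean_bg", f"{m}_mean_nobg"]
    for loss_name in losses_to_log or []:
        names.append(f"loss_{loss_name}")
    return names


def epoch_suite(probs: np.ndarray, truth: np.ndarray,
                losses_to_log: list[str] | None = None,
                loss_params=None, strict: bool = False) -> dict[str, float]:
    """Full named metric map for one epoch's predictions.

    ``probs`` is the SoftMax output (``... x classes``), ``truth`` the one-hot
    ground truth of the same shape.  Hard metrics are computed on the argmax
    of ``probs`` (ties break toward the lowest class index); each loss named
    in ``losses_to_log`` is evaluated on the probabilistic output.
    """
    from segsense.losses import LossParams, get_loss

    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(truth)
    n_classes = probs.shape[-1]
    pred = np.argmax(probs, axis=-1)
    true = np.argmax(truth, axis=-1)
    t = tally(pred, true, n_classes)
    rep = metric_report(t, strict=strict)

    out: dict[str, float] = {
        "accuracy": rep.accuracy,
        # identical after hard argmax; both logged for schema fidelity
        "categorical_accuracy": float(np.mean(pred == true)),
    }
    for m in ("dice", "jaccard", "precision", "recall"):
        for c in range(n_classes):
            out[f"{m}_c{c}"] = float(rep.per_class[m][c])
        out[f"{m}_mean_bg"] = rep.means[f"{m}_mean_bg"]
        out[f"{m}_mean_nobg"] = rep.means[f"{m}_mean_nobg"]
    params = loss_params if loss_params is not None else LossParams()
    for loss_name in losses_to_log or []:
        out[f"loss_{loss_name}"] = get_loss(loss_name)(probs, truth, params)
    return out
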