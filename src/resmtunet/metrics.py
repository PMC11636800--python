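"""Classification and segmentation metrics.

Classification: overall accuracy, macro-averaged F1, and precision / recall /
F1 for the invasive-carcinoma class, all derived from a confusion matrix
(rows = truth, columns = prediction).

Segmentation: per-sample per-class intersection-over-union and Dice
coefficient.  A class absent from both prediction and truth in a sample is
skipped for that sample's average, so background-only images do not inflate
scores.  Dataset aggregates are means over samples; the ``*_ic`` aggregates
average over the subset of samples whose ground truth contains invasive
carcinoma.  The background channel (label 0) is excluded from the headline
means by default.  For every sample-class pair Dice = 2*IoU / (1 + IoU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

IC_CLASS = 4          # invasive carcinoma mask label (last lesion class)
IC_INDEX = 3          # invasive carcinoma image-level class index


def confusion_matrix(y_true, y_pred, n_class: int) -> np.ndarray:
    """n_class x n_class count table, rows = truth, columns = prediction."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal shape")
    cm = np.zeros((n_class, n_class), dtype=np.int64)
    np.add.at(cm, (y_true.ravel(), y_pred.ravel()), 1)
    return cm


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero division in {what}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(cm: np.ndarray, ic_index: int = IC_INDEX) -> dict:
    """Acc, macro F1, and invasive-carcinoma precision/recall/F1 from a
    confusion matrix."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.shape[0]
    acc = cm.trace() / total
    precisions, recalls, f1s = [], [], []
    for c in range(n):
        p = _safe_div(cm[c, c], cm[:, c].sum(), f"precision of class {c}")
        r = _safe_div(cm[c, c], cm[c, :].sum(), f"recall of class {c}")
        f1 = _safe_div(2 * p * r, p + r, f"F1 of class {c}")
        precisions.append(p)
        recalls.append(r)
        f1s.append(f1)
    return {
        "acc": float(acc),
        "f1_macro": float(np.mean(f1s)),
        "p_ic": float(precisions[ic_index]),
        "r_ic": float(recalls[ic_index]),
        "f1_ic": float(f1s[ic_index]),
    }


@dataclass
class SegScore:
    """Per-sample per-class overlap scores and their dataset aggregates."""

    per_sample_iou: np.ndarray      # (n_samples, n_labels), NaN where skipped
    per_sample_dice: np.ndarray
    iou: float
    dice: float
    iou_ic: float
    dice_ic: float
    ic_samples: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _pair_scores(pred: np.ndarray, truth: np.ndarray, n_labels: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    iou = np.full(n_labels, np.nan)
    dice = np.full(n_labels, np.nan)
    for c in range(n_labels):
        p = pred == c
        t = truth == c
        ps, ts = int(p.sum()), int(t.sum())
        if ps == 0 and ts == 0:
            continue                      # class absent from both: skip
        inter = int(np.logical_and(p, t).sum())
        union = ps + ts - inter
        iou[c] = inter / union
        dice[c] = 2 * inter / (ps + ts)
    return iou, dice


def segmentation_metrics(preds, truths, n_labels: int, ic_class: int = IC_CLASS,
                         include_background: bool = False) -> SegScore:
    """Per-sample IoU/Dice per class plus dataset and invasive-carcinoma
    aggregates.

    ``preds``/``truths`` are sequences of congruent integer label masks with
    values in {0..n_labels-1}; label 0 is background.
    """
    if len(preds) != len(truths):
        raise ValueError("prediction and truth lists differ in length")
    ious, dices = [], []
    for p, t in zip(preds, truths):
        p = np.asarray(p)
        t = np.asarray(t)
        if p.shape != t.shape:
            raise ValueError(f"mask shape mismatch: {p.shape} vs {t.shape}")
        iou, dice = _pair_scores(p, t, n_labels)
        ious.append(iou)
        dices.append(dice)
    iou_arr = np.array(ious)
    dice_arr = np.array(dices)
    cols = slice(None) if include_background else slice(1, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN rows
        sample_iou = np.nanmean(iou_arr[:, cols], axis=1)
        sample_dice = np.nanmean(dice_arr[:, cols], axis=1)
    ic_samples = np.array([i for i, t in enumerate(truths)
                           if (np.asarray(t) == ic_class).any()], dtype=int)
    iou_ic = float(np.mean(iou_arr[ic_samples, ic_class])) if len(ic_samples) else float("nan")
    dice_ic = float(np.mean(dice_arr[ic_samples, ic_class])) if len(ic_samples) else float("nan")
    return SegScore(
        per_sample_iou=iou_arr,
        per_sample_dice=dice_arr,
        iou=float(np.nanmean(sample_iou)),
        dice=float(np.nanmean(sample_dice)),
        iou_ic=iou_ic,
        dice_ic=dice_ic,
        ic_samples=ic_samples,
    )
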