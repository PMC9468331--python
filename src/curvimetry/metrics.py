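"""Evaluation metrics for every stage of the pipeline.

Segmentation overlap (DSC, IoU, pixel accuracy) from per-pixel
confusion counts, binary cross-entropy on probability maps, detection
average precision (area under the all-points precision-recall curve,
IoU-matched at 0.5 by default), angle mean absolute error with the
per-model report layout, and the normal-approximation 95% confidence
half-width 1.96 * sqrt(psi (1 - psi) / N) for proportion-type metrics.
MAE, being unbounded, gets a t-interval over per-sample absolute
errors instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import BoundingBox, DetectionResult, as_mask

_BCE_EPS = 1e-7


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-pixel confusion counts between a predicted and a reference mask."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/TN/FN pixels; masks must have identical shape."""
    pred = as_mask(pred)
    gt = as_mask(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN)."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise ValueError("DSC undefined: both masks empty")
    return 2 * c.tp / denom


def iou(c: ConfusionCounts) -> float:
    """Intersection over union TP / (TP + FP + FN); always <= DSC."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        raise ValueError("IoU undefined: both masks empty")
    return c.tp / denom


def pixel_accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / all pixels."""
    if c.total == 0:
        raise ValueError("accuracy undefined: zero pixels")
    return (c.tp + c.tn) / c.total


def bce_loss(p: np.ndarray, gt: np.ndarray) -> float:
    """Mean binary cross-entropy (natural log) of a probability map.

    Probabilities are clipped to [1e-7, 1 - 1e-7] so exact 0/1
    predictions stay finite.
    """
    p = np.asarray(p, dtype=float)
    gt = as_mask(gt)
    if p.shape != gt.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs gt {gt.shape}")
    p = np.clip(p, _BCE_EPS, 1.0 - _BCE_EPS)
    y = gt.astype(float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def average_precision(
    detections: list[DetectionResult],
    gt_boxes: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> float:
    """AP: area under the all-points-interpolated precision-recall curve.

    Detections are processed in descending confidence; each is matched
    greedily to the unmatched ground-truth box of highest IoU at or
    above the threshold.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold={iou_threshold} outside (0, 1)")
    if not gt_boxes:
        return 0.0 if detections else 1.0
    if not detections:
        return 0.0
    order = sorted(range(len(detections)), key=lambda i: -detections[i].confidence)
    matched = [False] * len(gt_boxes)
    tp = np.zeros(len(detections))
    for rank, i in enumerate(order):
        box = detections[i].predicted_box
        best_j, best_iou = -1, iou_threshold
        for j, gt in enumerate(gt_boxes):
            if matched[j]:
                continue
            v = box.intersection_over_union(gt)
            if v >= best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched[best_j] = True
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(detections) + 1)
    recall = cum_tp / len(gt_boxes)
    # all-points interpolation: precision envelope, integrate over recall
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    recall = np.concatenate([[0.0], recall])
    prec_env = np.concatenate([[prec_env[0]], prec_env])
    return float(np.sum(np.diff(recall) * prec_env[1:]))


def map50(
    per_image: list[tuple[list[DetectionResult], list[BoundingBox]]],
    iou_threshold: float = 0.5,
) -> float:
    """Single-class mAP: mean per-image AP at one IoU threshold."""
    aps = [average_precision(d, g, iou_threshold) for d, g in per_image if g]
    if not aps:
        return 1.0 if all(not d for d, _ in per_image) else 0.0
    return float(np.mean(aps))


def mae(estimates, truths) -> float:
    """Mean absolute error between paired angle lists, in degrees."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.ndim != 1:
        raise ValueError(f"paired 1-D inputs required, got {est.shape} vs {tru.shape}")
    if est.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(est - tru)))


def ci95(psi: float, n: int) -> float:
    """95% CI half-width for a proportion-type metric psi on N samples."""
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi={psi} outside [0, 1]")
    if n < 1:
        raise ValueError(f"n={n} must be >= 1")
    return 1.96 * float(np.sqrt(psi * (1.0 - psi) / n))


def mae_ci95(estimates, truths) -> float:
    """t-interval 95% half-width over the per-sample absolute errors."""
    err = np.abs(np.asarray(estimates, float) - np.asarray(truths, float))
    n = err.size
    if n < 2:
        return float("nan")
    return float(stats.t.ppf(0.975, n - 1) * err.std(ddof=1) / np.sqrt(n))


def angle_report(estimates, truths) -> pd.DataFrame:
    """Per-model angle-recovery table plus an overall row.

    One row per ground-truth angle with the measurement mean, standard
    deviation, per-group MAE and sample count, and a final ``overall``
    row whose MAE is the mean over *all* samples (not the mean of
    per-group MAEs, which would differ for unbalanced groups).
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.size == 0:
        raise ValueError("paired nonempty inputs required")
    df = pd.DataFrame({"estimate": est, "truth": tru})
    rows = []
    for gt_angle, grp in df.groupby("truth", sort=True):
        rows.append(
            {
                "ground_truth": gt_angle,
                "mean": grp["estimate"].mean(),
                "std": grp["estimate"].std(ddof=1) if len(grp) > 1 else 0.0,
                "mae": float(np.mean(np.abs(grp["estimate"] - gt_angle))),
                "n": len(grp),
            }
        )
    rows.append(
        {
            "ground_truth": np.nan,
            "mean": np.nan,
            "std": np.nan,
            "mae": mae(est, tru),
            "n": est.size,
        }
    )
    return pd.DataFrame(rows)
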