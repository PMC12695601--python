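"""Instance-segmentation evaluation.

Predicted and ground-truth instances are matched one-to-one by descending
IoU at a fixed threshold; from the resulting TP/FP/FN counts the set-level
average precision AP = TP/(TP+FP+FN), precision, recall, F1 and the cell
number ratio CNR = predicted count / ground-truth count are derived.
Across a dataset, the summary reports the mean AP per IoU threshold and
the mean |1 - CNR| (perfect value 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse


@dataclass
class MatchResult:
    """One-to-one matching of predicted against ground-truth instances."""

    iou_threshold: float
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]]  # (pred_id, gt_id, iou)


@dataclass
class MetricSet:
    """Detection metrics for one image at one IoU threshold.

    ``None`` marks quantities undefined by division by zero (e.g. CNR on
    an empty ground truth).
    """

    iou_threshold: float
    ap: float
    precision: float | None
    recall: float | None
    f1: float | None
    cnr: float | None


@dataclass
class DatasetSummary:
    mean_ap: dict[float, float]  # per IoU threshold
    mean_abs_one_minus_cnr: float | None
    n_images: int


def iou_matrix(
    pred: np.ndarray, gt: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise IoU between all predicted and ground-truth instances.

    Returns ``(ious, pred_ids, gt_ids)`` where ``ious[i, j]`` is the IoU of
    ``pred_ids[i]`` with ``gt_ids[j]``.  Background (label 0) never
    participates.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    pred_ids = np.unique(pred[pred > 0])
    gt_ids = np.unique(gt[gt > 0])
    if len(pred_ids) == 0 or len(gt_ids) == 0:
        return np.zeros((len(pred_ids), len(gt_ids))), pred_ids, gt_ids
    # sparse confusion matrix of co-occurring (pred, gt) labels
    confusion = sparse.coo_matrix(
        (np.ones(pred.size), (pred.ravel(), gt.ravel())),
        shape=(int(pred.max()) + 1, int(gt.max()) + 1),
    ).tocsr()
    inter = confusion[pred_ids][:, gt_ids].toarray()
    pred_areas = np.bincount(pred.ravel())[pred_ids].astype(float)
    gt_areas = np.bincount(gt.ravel())[gt_ids].astype(float)
    union = pred_areas[:, None] + gt_areas[None, :] - inter
    return inter / union, pred_ids, gt_ids


def match_instances(
    ious: np.ndarray,
    threshold: float,
    pred_ids: Sequence[int] | None = None,
    gt_ids: Sequence[int] | None = None,
) -> MatchResult:
    """Greedy one-to-one matching by descending IoU.

    Pairs with IoU >= threshold are accepted in descending IoU order if
    both sides are still unmatched; ties break on (lower pred id, lower
    gt id).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"IoU threshold must lie in (0, 1], got {threshold}")
    ious = np.asarray(ious, dtype=float)
    n_pred, n_gt = ious.shape
    pred_ids = np.arange(n_pred) if pred_ids is None else np.asarray(pred_ids)
    gt_ids = np.arange(n_gt) if gt_ids is None else np.asarray(gt_ids)
    candidates = [
        (ious[i, j], i, j)
        for i in range(n_pred)
        for j in range(n_gt)
        if ious[i, j] >= threshold
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    pred_used = np.zeros(n_pred, dtype=bool)
    gt_used = np.zeros(n_gt, dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for iou, i, j in candidates:
        if pred_used[i] or gt_used[j]:
            continue
        pred_used[i] = True
        gt_used[j] = True
        pairs.append((int(pred_ids[i]), int(gt_ids[j]), float(iou)))
    tp = len(pairs)
    return MatchResult(
        iou_threshold=float(threshold),
        tp=tp,
        fp=n_pred - tp,
        fn=n_gt - tp,
        matched_pairs=pairs,
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall: 2PR / (P + R)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(match: MatchResult, pred_count: int, gt_count: int) -> MetricSet:
    """Derive AP, precision, recall, F1 and CNR from a match result.

    When both prediction and ground truth are empty, AP, precision, recall
    and F1 are defined as 1 by convention; other division-by-zero cases
    come back as ``None`` with a warning.
    """
    if pred_count < 0 or gt_count < 0:
        raise ValueError("instance counts must be non-negative")
    tp, fp, fn = match.tp, match.fp, match.fn
    if pred_count == 0 and gt_count == 0:
        return MetricSet(match.iou_threshold, ap=1.0, precision=1.0, recall=1.0, f1=1.0, cnr=None)
    ap = tp / (tp + fp + fn)
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is None or recall is None:
        warnings.warn("precision/recall undefined for an empty side", stacklevel=2)
        f1 = None
    else:
        f1 = f1_score(precision, recall)
    if gt_count > 0:
        cnr = pred_count / gt_count
    else:
        warnings.warn("CNR undefined: empty ground truth", stacklevel=2)
        cnr = None
    return MetricSet(match.iou_threshold, ap=ap, precision=precision, recall=recall, f1=f1, cnr=cnr)


def evaluate_masks(
    pred: np.ndarray, gt: np.ndarray, thresholds: Sequence[float] = (0.5,)
) -> list[MetricSet]:
    """Metrics for one predicted/ground-truth label-map pair at each threshold."""
    ious, pred_ids, gt_ids = iou_matrix(pred, gt)
    out = []
    for threshold in thresholds:
        match = match_instances(ious, threshold, pred_ids, gt_ids)
        out.append(compute_metrics(match, len(pred_ids), len(gt_ids)))
    return out


def dataset_summary(metric_sets: Sequence[MetricSet]) -> DatasetSummary:
    """Aggregate per-image metrics: mean AP per threshold, mean |1 - CNR|."""
    metric_sets = list(metric_sets)
    if not metric_sets:
        raise ValueError("dataset_summary requires at least one MetricSet")
    by_threshold: dict[float, list[float]] = {}
    for ms in metric_sets:
        by_threshold.setdefault(ms.iou_threshold, []).append(ms.ap)
    mean_ap = {t: float(np.mean(v)) for t, v in by_threshold.items()}
    cnrs = [ms.cnr for ms in metric_sets if ms.cnr is not None]
    mean_dev = float(np.mean([abs(1.0 - c) for c in cnrs])) if cnrs else None
    return DatasetSummary(mean_ap=mean_ap, mean_abs_one_minus_cnr=mean_dev, n_images=len(metric_sets))
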