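"""Segmentation and measurement evaluation.

Instance-segmentation quality is scored the COCO way: detections are greedily
matched to ground truth by mask IoU at a threshold, precision = TP/(TP+FP) and
recall = TP/(TP+FN) accumulate down the score-ranked detection list, AP is the
area under the interpolated precision-recall envelope (101-point rule), and
mAP averages AP over IoU thresholds 0.50, 0.55, ..., 0.95.

Measurement quality uses the summary-statistics conventions of the bundled
field-trial tables: population (divisor-n) standard deviation, SD expressed as
percent of the mean, and mean accuracy = mean of 100·(1 − relative error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import FormatError, InsufficientDataError, PairingError
from .io_formats import InstanceMask

#: COCO threshold grid: 0.50 to 0.95 in steps of 0.05.
MAP_THRESHOLDS = np.round(np.arange(0.50, 1.00, 0.05), 2)

#: Recall grid of the 101-point AP interpolation.
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class MatchResult:
    """Detection-truth matching outcome at one IoU threshold."""

    true_positives: int
    false_positives: int
    false_negatives: int
    iou_threshold: float
    # cumulative precision/recall down the score-ranked detection list,
    # with a 1/0 flag per detection marking it TP
    precision: tuple[float, ...] = ()
    recall: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if min(self.true_positives, self.false_positives, self.false_negatives) < 0:
            raise ValueError("counts must be non-negative")


def mask_iou(a: InstanceMask, b: InstanceMask) -> float:
    """Intersection over union of two co-registered binary masks."""
    if a.raster.shape != b.raster.shape:
        raise FormatError(
            f"mask shapes differ: {a.raster.shape} vs {b.raster.shape}"
        )
    inter = np.count_nonzero(a.raster & b.raster)
    union = np.count_nonzero(a.raster | b.raster)
    return inter / union


def match_instances(
    detections: Sequence[InstanceMask],
    truths: Sequence[InstanceMask],
    iou_threshold: float,
) -> MatchResult:
    """Greedy COCO-style matching of detections to ground-truth instances.

    Detections are visited in descending score order (unscored detections
    count as score 1, stable order); each claims the unmatched truth with the
    highest IoU ≥ threshold (TP) or becomes an FP. Unmatched truths are FN.
    """
    order = sorted(
        range(len(detections)),
        key=lambda i: -(detections[i].score if detections[i].score is not None else 1.0),
    )
    matched_truth: set[int] = set()
    tp_flags: list[bool] = []
    for i in order:
        det = detections[i]
        best_iou, best_j = 0.0, -1
        for j, truth in enumerate(truths):
            if j in matched_truth:
                continue
            iou = mask_iou(det, truth)
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0:
            matched_truth.add(best_j)
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum([not f for f in tp_flags])
    n_truth = len(truths)
    with np.errstate(invalid="ignore"):
        precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_truth if n_truth else np.zeros_like(tp_cum, dtype=float)
    tp = int(tp_cum[-1]) if len(tp_flags) else 0
    return MatchResult(
        true_positives=tp,
        false_positives=len(detections) - tp,
        false_negatives=n_truth - tp,
        iou_threshold=iou_threshold,
        precision=tuple(np.atleast_1d(precision).tolist()),
        recall=tuple(np.atleast_1d(recall).tolist()),
    )


def average_precision(match: MatchResult) -> float:
    """AP: area under the precision envelope, 101-point interpolation.

    At each recall level r of the grid, the interpolated precision is the
    maximum precision attained at recall ≥ r (zero when unreached); AP is the
    mean over the grid.
    """
    if not match.precision:
        return 0.0
    rec = np.asarray(match.recall)
    prec = np.asarray(match.precision)
    # precision envelope: running max from the right
    env = np.maximum.accumulate(prec[::-1])[::-1]
    ap = 0.0
    for r in RECALL_GRID:
        above = rec >= r - 1e-12
        ap += env[above].max() if above.any() else 0.0
    return ap / len(RECALL_GRID)


def map_range(
    detections: Sequence[InstanceMask],
    truths: Sequence[InstanceMask],
    thresholds: Sequence[float] = tuple(MAP_THRESHOLDS),
) -> tuple[float, dict[float, float]]:
    """mAP over the IoU-threshold grid; returns (mAP, AP-per-threshold)."""
    ap_at = {
        float(t): average_precision(match_instances(detections, truths, float(t)))
        for t in thresholds
    }
    return float(np.mean(list(ap_at.values()))), ap_at


def accuracy_stats(
    reference: Sequence[float], estimate: Sequence[float]
) -> float:
    """Mean accuracy (%) of paired estimates against reference values.

    Per-item accuracy is 100·(1 − |estimate − reference| / reference), floored
    at zero; the result is the mean over items.
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise PairingError(f"length mismatch: {ref.shape} vs {est.shape}")
    if np.any(ref <= 0):
        raise ValueError("reference values must be positive")
    acc = np.maximum(0.0, 100.0 * (1.0 - np.abs(est - ref) / ref))
    return float(acc.mean())


def column_stats(values: Sequence[float]) -> tuple[float, float, float]:
    """(mean, population SD, SD as percent of mean) of a measurement column."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("need at least 2 values for a spread")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=0))
    return mean, sd, 100.0 * sd / mean
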