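"""Detection evaluation: IoU matching, VOC2010 average precision, F1 sweep.

Matching follows the PASCAL VOC protocol: detections are processed in
confidence-descending order (ties broken by lower cx, then cy); each is a
true positive if its best-IoU *unmatched* ground-truth box reaches the IoU
threshold, otherwise a false positive — so subsequent detections of an
already-matched ground truth count as false positives.  Because the
synthesized boxes are only loosely centered on the human click marks, the
pipeline's default matching threshold is a permissive IoU of 0.1.

Average precision is the VOC2010 definition: the exact area under the
monotonically non-increasing precision envelope of the confidence-ranked
precision-recall curve.  With a single object class, mAP equals AP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation_io import DetectionRecord, sort_detections
from .tiles import GTBox

__all__ = [
    "MatchTable",
    "PRCurve",
    "SweepRow",
    "iou",
    "match",
    "average_precision",
    "precision_recall_f1",
    "sweep_thresholds",
]

DEFAULT_IOU_THRESHOLD = 0.1
DEFAULT_SWEEP_STEP = 0.05


@dataclass
class MatchTable:
    """Confidence-ranked detections flagged TP/FP against a ground-truth set."""

    detections: list[DetectionRecord]  # ranked, confidence descending
    is_tp: list[bool]
    n_ground_truth: int
    iou_threshold: float

    @property
    def n_tp(self) -> int:
        return sum(self.is_tp)

    @property
    def n_fp(self) -> int:
        return len(self.is_tp) - self.n_tp


@dataclass
class PRCurve:
    """Precision/recall by rank plus the interpolated envelope and its area."""

    recall: np.ndarray
    precision: np.ndarray
    envelope: np.ndarray
    ap: float


@dataclass
class SweepRow:
    threshold: float
    precision: float
    recall: float
    f1: float


def _corners(box) -> tuple[float, float, float, float]:
    return (box.cx - box.w / 2.0, box.cy - box.h / 2.0,
            box.cx + box.w / 2.0, box.cy + box.h / 2.0)


def iou(a, b) -> float:
    """Intersection over union of two center/size boxes, on continuous geometry."""
    ax0, ay0, ax1, ay1 = _corners(a)
    bx0, by0, bx1, by1 = _corners(b)
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def match(
    dets: list[DetectionRecord],
    gts: list[GTBox],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchTable:
    """Greedily assign detections to ground truth in confidence order.

    Each ground-truth box can be matched at most once; the assignment for a
    detection is its highest-IoU unmatched ground truth (ties to the earlier
    box in the list).
    """
    ranked = sort_detections(dets)
    matched = [False] * len(gts)
    flags: list[bool] = []
    for det in ranked:
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if matched[j]:
                continue
            v = iou(det, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return MatchTable(ranked, flags, len(gts), iou_threshold)


def average_precision(table: MatchTable) -> PRCurve:
    """VOC2010 AP: exact area under the monotone precision envelope."""
    if table.n_ground_truth < 1:
        raise ValueError("average precision undefined with zero ground-truth boxes")
    flags = np.asarray(table.is_tp, dtype=float)
    if flags.size == 0:
        return PRCurve(np.array([]), np.array([]), np.array([]), 0.0)
    tp_cum = np.cumsum(flags)
    ranks = np.arange(1, flags.size + 1)
    recall = tp_cum / table.n_ground_truth
    precision = tp_cum / ranks
    # envelope: running max of precision from the highest recall backwards
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    # sum precision over steps where recall increases
    prev_r = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - prev_r) * envelope))
    return PRCurve(recall, precision, envelope, ap)


def precision_recall_f1(table: MatchTable) -> tuple[float, float, float]:
    """Operating-point P/R/F1 with 0/0 guarded to 0."""
    n_det = len(table.is_tp)
    tp = table.n_tp
    precision = tp / n_det if n_det > 0 else 0.0
    recall = tp / table.n_ground_truth if table.n_ground_truth > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def sweep_thresholds(
    dets: list[DetectionRecord],
    gts: list[GTBox],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    step: float = DEFAULT_SWEEP_STEP,
) -> tuple[list[SweepRow], float]:
    """P/R/F1 at every detection threshold 0, step, ..., 1.

    Detections with confidence >= threshold are kept.  Returns the sweep
    table and the F1-maximizing threshold (ties go to the lower threshold).
    """
    if not 0.0 < step <= 1.0:
        raise ValueError("step must be in (0, 1]")
    thresholds = np.arange(0.0, 1.0 + step / 2.0, step)
    thresholds[-1] = min(thresholds[-1], 1.0)
    rows: list[SweepRow] = []
    best_t, best_f1 = 0.0, -1.0
    for t in thresholds:
        kept = [d for d in dets if d.confidence >= t]
        p, r, f1 = precision_recall_f1(match(kept, gts, iou_threshold))
        rows.append(SweepRow(float(t), p, r, f1))
        if f1 > best_f1 + 1e-12:
            best_f1, best_t = f1, float(t)
    return rows, best_t
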