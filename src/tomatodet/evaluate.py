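"""Detection evaluation: greedy cIOU matching, P/R/F1, interpolated AP,
PR curves, and condition-stratified identification rates.

A detection counts as a true positive when it claims a previously
unclaimed ground-truth circle with cIOU at or above the matching threshold
(default 0.5), walking detections in descending confidence.  The PR curve
sweeps every distinct confidence value; AP is the all-point interpolated
area ``sum (r_{n+1} - r_n) * max_{r >= r_{n+1}} p(r)``.  Stratified tables
follow the convention in which the correct and missed rates are divided by
the stratum's ground-truth count while the false rate is divided by the
stratum's detection count (TP + FP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .decode import DetectionSet
from .geometry import Circle, ciou_matrix

__all__ = [
    "EvalReport",
    "match_detections",
    "precision_recall_f1",
    "f1_score",
    "pr_curve",
    "average_precision",
    "stratified_rates",
    "evaluate_detections",
    "round2",
]


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (table convention)."""
    return math.floor(abs(x) * 100.0 + 0.5) / 100.0 * (1 if x >= 0 else -1)


@dataclass
class EvalReport:
    """Matched counts, summary metrics and stratified rate tables."""

    tp: int
    fp: int
    fn: int
    precision: float  # percent
    recall: float
    f1: float
    ap: float
    pr_curve: list[tuple[float, float]] = field(default_factory=list)
    operating_point: tuple[float, float] = (0.0, 0.0)  # (recall, precision) %
    strata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision_pct": self.precision,
            "recall_pct": self.recall,
            "f1_pct": self.f1,
            "ap_pct": self.ap,
            "operating_point": {
                "recall_pct": self.operating_point[0],
                "precision_pct": self.operating_point[1],
            },
            "strata": self.strata,
        }


def _params(circles: list[Circle]) -> np.ndarray:
    return np.array([[c.cx, c.cy, c.r] for c in circles], dtype=np.float64).reshape(-1, 3)


def match_detections(
    dets: DetectionSet | list[Circle],
    gts: list[Circle],
    ciou_threshold: float = 0.5,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy one-to-one matching in descending confidence order.

    Each detection claims the unclaimed ground truth of highest cIOU at or
    above the threshold; leftovers are FP (detections) and FN (ground
    truths).  Returns ``(TP, FP, FN, matches)`` with matches as
    ``(det_index, gt_index)`` pairs into the original lists.
    """
    if not 0.0 < ciou_threshold < 1.0:
        raise ValueError(f"ciou_threshold must lie in (0, 1), got {ciou_threshold}")
    det_list = list(dets.circles if isinstance(dets, DetectionSet) else dets)
    order = sorted(
        range(len(det_list)),
        key=lambda i: (-(det_list[i].score if det_list[i].score is not None else 1.0), i),
    )
    iou = ciou_matrix(_params(det_list), _params(gts))
    claimed = [False] * len(gts)
    matches: list[tuple[int, int]] = []
    for di in order:
        best_gt, best_iou = -1, ciou_threshold
        for gi in range(len(gts)):
            if not claimed[gi] and iou[di, gi] >= best_iou:
                best_gt, best_iou = gi, iou[di, gi]
        if best_gt >= 0:
            claimed[best_gt] = True
            matches.append((di, best_gt))
    tp = len(matches)
    return tp, len(det_list) - tp, len(gts) - tp, matches


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1, each in percent (0 when undefined)."""
    p = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2.0 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def f1_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall given in percent."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def pr_curve(
    per_image: list[tuple[DetectionSet | list[Circle], list[Circle]]],
    ciou_threshold: float = 0.5,
) -> list[tuple[float, float]]:
    """Pooled precision-recall pairs over descending score thresholds.

    Detections from all images are ranked by confidence; each is flagged
    TP/FP by greedy matching within its image in that global order, then
    cumulative precision and recall are emitted at every distinct score.
    Recall is non-decreasing along the returned list.
    """
    scored = []  # (score, image_index, det_index)
    gts_per_image = []
    dets_per_image = []
    for img_idx, (dets, gts) in enumerate(per_image):
        det_list = list(dets.circles if isinstance(dets, DetectionSet) else dets)
        dets_per_image.append(det_list)
        gts_per_image.append(gts)
        for di, d in enumerate(det_list):
            scored.append((d.score if d.score is not None else 1.0, img_idx, di))
    n_gt = sum(len(g) for g in gts_per_image)
    if n_gt == 0 or not scored:
        return []
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    iou_mats = [
        ciou_matrix(_params(d), _params(g)) for d, g in zip(dets_per_image, gts_per_image)
    ]
    claimed = [[False] * len(g) for g in gts_per_image]
    flags = []
    for score, img_idx, di in scored:
        iou = iou_mats[img_idx]
        best_gt, best_iou = -1, ciou_threshold
        for gi in range(len(gts_per_image[img_idx])):
            if not claimed[img_idx][gi] and iou[di, gi] >= best_iou:
                best_gt, best_iou = gi, iou[di, gi]
        if best_gt >= 0:
            claimed[img_idx][best_gt] = True
            flags.append((score, True))
        else:
            flags.append((score, False))
    curve = []
    tp = fp = 0
    for i, (score, is_tp) in enumerate(flags):
        tp += is_tp
        fp += not is_tp
        last_of_score = i + 1 == len(flags) or flags[i + 1][0] != score
        if last_of_score:
            curve.append((tp / n_gt, tp / (tp + fp)))
    return curve


def average_precision(curve: list[tuple[float, float]]) -> float:
    """All-point interpolated AP in percent.

    ``AP = sum_n (r_{n+1} - r_n) p_interp(r_{n+1})`` with
    ``p_interp(r) = max over the curve at recall >= r`` and r_0 = 0.
    """
    if not curve:
        return 0.0
    pts = sorted(curve)
    recalls = np.array([r for r, _ in pts])
    precisions = np.array([p for _, p in pts])
    # suffix max: best precision at or beyond each recall
    p_interp = np.maximum.accumulate(precisions[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recalls, p_interp):
        ap += (r - prev_r) * p
        prev_r = r
    return 100.0 * ap


def stratified_rates(
    gt_labels: list[str],
    gt_matched: list[bool],
    fp_labels: list[str],
) -> dict[str, dict[str, float]]:
    """Per-stratum identification-rate table.

    ``gt_labels``/``gt_matched`` describe every ground-truth object and
    whether it was claimed; ``fp_labels`` carries one stratum label per
    false-positive detection.  Per stratum with GT count > 0:
    ``correct = 100*TP/GT``, ``missed = 100*FN/GT`` (they sum to 100), and
    ``false = 100*FP/(TP+FP)`` — the rate of detections in that stratum
    that match nothing.  Strata with no ground truth are omitted.
    """
    strata: dict[str, dict[str, float]] = {}
    labels = sorted(set(gt_labels) | set(fp_labels))
    for lab in labels:
        gt_n = sum(1 for g in gt_labels if g == lab)
        if gt_n == 0:
            continue
        tp = sum(1 for g, m in zip(gt_labels, gt_matched) if g == lab and m)
        fp = sum(1 for f in fp_labels if f == lab)
        fn = gt_n - tp
        strata[lab] = {
            "gt": gt_n,
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "correct_rate": round2(100.0 * tp / gt_n),
            "missed_rate": round2(100.0 * fn / gt_n),
            "false_rate": round2(100.0 * fp / (tp + fp)) if tp + fp > 0 else 0.0,
        }
    return strata


def evaluate_detections(
    per_image: list[tuple[DetectionSet | list[Circle], list[Circle]]],
    ciou_threshold: float = 0.5,
    confidence_threshold: float = 0.6,
    gt_condition_labels: list[list[dict[str, str]]] | None = None,
) -> EvalReport:
    """Full report over a test set.

    Summary P/R/F1 and the stratified tables are computed at the
    confidence operating point (default 0.6); the PR curve and AP use all
    pooled detections.  ``gt_condition_labels``, when given, holds one
    ``{"lighting": ..., "occlusion": ...}`` dict per ground-truth circle
    per image; false positives inherit the image's lighting label and the
    occlusion label of the most-overlapping ground truth (falling back to
    "slight" in images without ground truth).
    """
    curve = pr_curve(per_image, ciou_threshold)
    ap = average_precision(curve)

    tp = fp = fn = 0
    gt_labels_light, gt_labels_occ, gt_matched = [], [], []
    fp_labels_light, fp_labels_occ = [], []
    for img_idx, (dets, gts) in enumerate(per_image):
        det_list = [
            d
            for d in (dets.circles if isinstance(dets, DetectionSet) else dets)
            if (d.score if d.score is not None else 1.0) >= confidence_threshold
        ]
        itp, ifp, ifn, matches = match_detections(det_list, gts, ciou_threshold)
        tp, fp, fn = tp + itp, fp + ifp, fn + ifn
        if gt_condition_labels is None:
            continue
        labels = gt_condition_labels[img_idx]
        matched_gt = {gi for _, gi in matches}
        matched_det = {di for di, _ in matches}
        for gi in range(len(gts)):
            gt_labels_light.append(labels[gi]["lighting"])
            gt_labels_occ.append(labels[gi]["occlusion"])
            gt_matched.append(gi in matched_gt)
        if len(matched_det) < len(det_list):
            iou = ciou_matrix(_params(det_list), _params(gts))
            for di in range(len(det_list)):
                if di in matched_det:
                    continue
                if gts:
                    gi = int(np.argmax(iou[di]))
                    fp_labels_light.append(labels[gi]["lighting"])
                    fp_labels_occ.append(labels[gi]["occlusion"])
                else:
                    img_light = labels[0]["lighting"] if labels else "sunlight"
                    fp_labels_light.append(img_light)
                    fp_labels_occ.append("slight")

    p, r, f1 = precision_recall_f1(tp, fp, fn)
    strata = {}
    if gt_condition_labels is not None:
        strata = {
            "lighting": stratified_rates(gt_labels_light, gt_matched, fp_labels_light),
            "occlusion": stratified_rates(gt_labels_occ, gt_matched, fp_labels_occ),
        }
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=round2(p),
        recall=round2(r),
        f1=round2(f1),
        ap=round2(ap),
        pr_curve=curve,
        operating_point=(round2(r), round2(p)),
        strata=strata,
    )
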