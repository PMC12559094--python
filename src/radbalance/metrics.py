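"""Classification and detection performance metrics.

Classification: confusion matrix at a score threshold, precision / recall /
accuracy / F1 (zero denominators yield NaN, never an exception),
support-weighted two-class averages, and ROC AUC with a DeLong or bootstrap
95% confidence interval.

Detection: IoU, greedy confidence-ordered one-to-one matching of detections
to ground-truth boxes, and COCO-style average precision — AP at a single IoU
threshold via 101-point interpolation of the precision-recall curve, and
AP50-95 as the mean over IoU thresholds 0.50 to 0.95 in steps of 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .cohort import BoundingBox, ClassScore, Detection, ImageRecord

__all__ = [
    "ConfusionMatrix",
    "ClassificationMetrics",
    "ROCResult",
    "APResult",
    "MatchResult",
    "confusion_matrix",
    "classification_metrics",
    "weighted_metrics",
    "roc_auc",
    "iou",
    "match_detections",
    "average_precision",
    "ap50_95",
    "IOU_SWEEP",
]

#: IoU thresholds for the AP50-95 sweep.
IOU_SWEEP = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))

UNDEFINED = math.nan


def _is_defined(x: float) -> bool:
    return not math.isnan(x)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassificationMetrics:
    """Per-class (fracture-positive) and support-weighted two-class metrics.

    Undefined ratios (zero denominator) are NaN.
    """

    precision: float = UNDEFINED
    recall: float = UNDEFINED
    accuracy: float = UNDEFINED
    f1: float = UNDEFINED
    weighted_precision: float = UNDEFINED
    weighted_recall: float = UNDEFINED
    weighted_f1: float = UNDEFINED


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float


@dataclass
class APResult:
    ap_by_iou: dict[float, float]
    ap50: float
    ap50_95: float
    pr_points: dict[float, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


@dataclass
class MatchResult:
    """Greedy matching outcome: detections sorted as processed, TP flags, FN count."""

    detections: list[Detection]
    tp_flags: np.ndarray
    n_fn: int
    n_truth: int


# ---------------------------------------------------------------------------
# classification


def _score_map(scores: Sequence[ClassScore]) -> dict[str, float]:
    return {s.image_id: s.score for s in scores}


def confusion_matrix(
    scores: Sequence[ClassScore],
    records: Sequence[ImageRecord],
    threshold: float = 0.5,
) -> ConfusionMatrix:
    """Tally predicted fracture presence (score >= threshold) against the labels."""
    by_id = _score_map(scores)
    tp = fp = fn = tn = 0
    for r in records:
        try:
            s = by_id[r.image_id]
        except KeyError:
            raise KeyError(f"no score for image {r.image_id!r}") from None
        pred = s >= threshold
        if r.fracture:
            tp += pred
            fn += not pred
        else:
            fp += pred
            tn += not pred
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def classification_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """P = TP/(TP+FP), R = TP/(TP+FN), A = (TP+TN)/total, F1 = 2PR/(P+R)."""
    p = _ratio(cm.tp, cm.tp + cm.fp)
    r = _ratio(cm.tp, cm.tp + cm.fn)
    a = _ratio(cm.tp + cm.tn, cm.total)
    if _is_defined(p) and _is_defined(r) and (p + r) > 0:
        f1 = 2.0 * p * r / (p + r)
    else:
        f1 = UNDEFINED
    return ClassificationMetrics(precision=p, recall=r, accuracy=a, f1=f1)


def weighted_metrics(
    scores: Sequence[ClassScore],
    records: Sequence[ImageRecord],
    threshold: float = 0.5,
) -> ClassificationMetrics:
    """Per-class metrics plus support-weighted two-class averages.

    Both classes (fracture, no-fracture) are scored as the positive class in
    turn; the weighted figures average them by class support.  Classes whose
    metric is undefined are skipped with a warning.
    """
    if not records:
        raise ValueError("no records to evaluate")
    cm = confusion_matrix(scores, records, threshold)
    pos = classification_metrics(cm)
    # no-fracture as the positive class: swap roles
    neg = classification_metrics(ConfusionMatrix(tp=cm.tn, fp=cm.fn, fn=cm.fp, tn=cm.tp))
    support_pos = cm.tp + cm.fn
    support_neg = cm.tn + cm.fp

    def wavg(vp: float, vn: float) -> float:
        pairs = [
            (v, w) for v, w in ((vp, support_pos), (vn, support_neg)) if _is_defined(v) and w > 0
        ]
        if len(pairs) < 2 and support_pos > 0 and support_neg > 0:
            warnings.warn("a class metric is undefined; weighted average skips it")
        if not pairs:
            return UNDEFINED
        tot = sum(w for _, w in pairs)
        return sum(v * w for v, w in pairs) / tot

    out = ClassificationMetrics(
        precision=pos.precision,
        recall=pos.recall,
        accuracy=pos.accuracy,
        f1=pos.f1,
        weighted_precision=wavg(pos.precision, neg.precision),
        weighted_recall=wavg(pos.recall, neg.recall),
        weighted_f1=wavg(pos.f1, neg.f1),
    )
    return out


def _delong_ci(
    pos_scores: np.ndarray, neg_scores: np.ndarray, auc: float, alpha: float = 0.05
) -> tuple[float, float]:
    """DeLong variance of the AUC via midranks; Wald interval clipped to [0, 1]."""
    m, n = len(pos_scores), len(neg_scores)
    all_scores = np.concatenate([pos_scores, neg_scores])
    rank_all = sps.rankdata(all_scores)
    rank_pos = sps.rankdata(pos_scores)
    rank_neg = sps.rankdata(neg_scores)
    # structural components: v10_i = P(pos_i outranks a random negative), ties half
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


def roc_auc(
    scores: Sequence[ClassScore],
    records: Sequence[ImageRecord],
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """ROC curve and AUC with a 95% confidence interval.

    The AUC equals the probability that a random fracture image outscores a
    random non-fracture image, ties counted half (the Mann-Whitney statistic).
    ``ci_method`` is ``"delong"`` (default) or ``"bootstrap"`` (seeded,
    ``n_boot`` resamples of images).
    """
    by_id = _score_map(scores)
    y = np.array([r.fracture for r in records], dtype=bool)
    s = np.array([by_id[r.image_id] for r in records], dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    pos, neg = s[y], s[~y]
    if ci_method == "delong":
        lo, hi = _delong_ci(pos, neg, auc)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        vals = []
        idx = np.arange(len(s))
        for _ in range(n_boot):
            b = rng.choice(idx, size=len(idx), replace=True)
            yb, sb = y[b], s[b]
            if yb.all() or not yb.any():
                continue
            pb, nb = sb[yb], sb[~yb]
            # pairwise Mann-Whitney on the resample via rank formula
            ranks = sps.rankdata(np.concatenate([pb, nb]))
            u = ranks[: len(pb)].sum() - len(pb) * (len(pb) + 1) / 2.0
            vals.append(u / (len(pb) * len(nb)))
        lo, hi = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# detection


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two corner-coded boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _det_sort_key(d: Detection):
    # descending confidence; ties broken by image_id then coordinates for determinism
    return (-d.confidence, d.image_id, d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max)


def match_detections(
    dets: Sequence[Detection],
    truths: Mapping[str, Sequence[BoundingBox]],
    iou_threshold: float,
) -> MatchResult:
    """Greedy one-to-one assignment of detections to ground-truth boxes.

    Within each image, detections are processed in descending confidence; a
    detection is a TP if its best-IoU not-yet-consumed truth reaches the
    threshold (that truth is then consumed), else an FP.  Truths never
    consumed are FNs.
    """
    order = sorted(dets, key=_det_sort_key)
    consumed: dict[str, list[bool]] = {
        img: [False] * len(boxes) for img, boxes in truths.items()
    }
    flags = np.zeros(len(order), dtype=bool)
    for i, d in enumerate(order):
        boxes = truths.get(d.image_id, ())
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(boxes):
            if consumed[d.image_id][j]:
                continue
            v = iou(d.box, t)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            consumed[d.image_id][best_j] = True
            flags[i] = True
    n_truth = sum(len(b) for b in truths.values())
    n_fn = n_truth - int(flags.sum())
    return MatchResult(detections=order, tp_flags=flags, n_fn=n_fn, n_truth=n_truth)


def _pr_curve(match: MatchResult) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative precision/recall over confidence-sorted pooled detections."""
    tp_cum = np.cumsum(match.tp_flags)
    k = np.arange(1, len(match.tp_flags) + 1)
    precision = tp_cum / k
    recall = tp_cum / match.n_truth
    return precision, recall


def _ap_101(precision: np.ndarray, recall: np.ndarray) -> float:
    """101-point interpolated AP: mean of the precision envelope at recalls 0..1."""
    if len(precision) == 0:
        return 0.0
    # monotone non-increasing precision envelope (right-to-left running max)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    grid = np.linspace(0.0, 1.0, 101)
    # for each grid recall, the envelope at the first point with recall >= r (else 0)
    idx = np.searchsorted(recall, grid, side="left")
    vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(vals.mean())


def average_precision(
    dets: Sequence[Detection],
    truths: Mapping[str, Sequence[BoundingBox]],
    iou_threshold: float,
) -> float:
    """AP at one IoU threshold, pooled over images, 101-point interpolation."""
    n_truth = sum(len(b) for b in truths.values())
    if n_truth == 0:
        raise ValueError("average precision needs at least one ground-truth box")
    if not dets:
        return 0.0
    match = match_detections(dets, truths, iou_threshold)
    precision, recall = _pr_curve(match)
    return _ap_101(precision, recall)


def ap50_95(
    dets: Sequence[Detection], truths: Mapping[str, Sequence[BoundingBox]]
) -> APResult:
    """AP swept over IoU 0.50..0.95 (step 0.05), with per-threshold PR points."""
    n_truth = sum(len(b) for b in truths.values())
    if n_truth == 0:
        raise ValueError("average precision needs at least one ground-truth box")
    ap_by_iou: dict[float, float] = {}
    pr_points: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for thr in IOU_SWEEP:
        if dets:
            match = match_detections(dets, truths, float(thr))
            precision, recall = _pr_curve(match)
            ap_by_iou[float(thr)] = _ap_101(precision, recall)
            pr_points[float(thr)] = (precision, recall)
        else:
            ap_by_iou[float(thr)] = 0.0
            pr_points[float(thr)] = (np.array([]), np.array([]))
    ap50 = ap_by_iou[0.5]
    mean_ap = float(np.mean(list(ap_by_iou.values())))
    return APResult(ap_by_iou=ap_by_iou, ap50=ap50, ap50_95=mean_ap, pr_points=pr_points)
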