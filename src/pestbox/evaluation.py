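"""Detection and counting metrics.

Detection metrics follow the PASCAL VOC protocol: detections at or above a
confidence threshold (0.5 by default) are matched greedily per image and
class — descending confidence, each detection claiming the highest-IoU
unmatched annotation with IoU at or above the threshold (0.5 by default).
Matched detections are true positives, the rest false positives, unmatched
annotations false negatives.  AP is the area under the interpolated
precision envelope over recall, ranked over *all* detections (no confidence
floor); macro means over classes give mAP, mPrecision, mRecall and mF1.
Classes with no annotations have undefined AP and are excluded from the
macro means with a warning.

Counting metrics compare per-image predicted counts (retained detections at
or above the confidence threshold, all classes pooled) with ground-truth
counts: RMSE, the coefficient of determination R^2 computed against the
ground-truth counts, an ordinary least-squares regression of predicted on
true counts, and a signed-error histogram with unit-width integer bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .geometry import Annotation, Detection, pairwise_iou

__all__ = [
    "MatchResult",
    "ClassMetrics",
    "CountingReport",
    "match_detections",
    "precision_recall",
    "f1_score",
    "average_precision",
    "evaluate_detections",
    "summarize",
    "counting_pairs",
    "counting_metrics",
]


@dataclass
class MatchResult:
    """Outcome of matching detections against annotations.

    ``det_indices`` are the indices (into the input list) of detections above
    the confidence threshold, and ``det_is_tp`` labels each of them;
    ``annot_matched`` is aligned with the input annotations.
    """

    det_indices: np.ndarray
    det_is_tp: np.ndarray
    annot_matched: np.ndarray
    class_counts: dict[int, tuple[int, int, int]]  # class_id -> (tp, fp, fn)

    @property
    def tp(self) -> int:
        return int(self.det_is_tp.sum())

    @property
    def fp(self) -> int:
        return int((~self.det_is_tp).sum())

    @property
    def fn(self) -> int:
        return int((~self.annot_matched).sum())


def _greedy_match(
    dets: Sequence[Detection],
    det_idx: Sequence[int],
    annots: Sequence[Annotation],
    annot_idx: Sequence[int],
    iou_threshold: float,
    is_tp: np.ndarray,
    matched: np.ndarray,
) -> None:
    """Greedy claim of annotations by detections within one image+class group.

    Detections are visited in descending confidence (stable in input order);
    each claims its highest-IoU unmatched annotation at or above the IoU
    threshold, ties broken by annotation input order.
    """
    if not annot_idx:
        return
    det_boxes = np.array([dets[i].box.as_tuple() for i in det_idx])
    ann_boxes = np.array([annots[j].box.as_tuple() for j in annot_idx])
    ious = pairwise_iou(det_boxes, ann_boxes)
    order = sorted(range(len(det_idx)), key=lambda r: (-dets[det_idx[r]].confidence, det_idx[r]))
    taken = np.zeros(len(annot_idx), dtype=bool)
    for r in order:
        candidates = np.flatnonzero(~taken & (ious[r] >= iou_threshold))
        if candidates.size == 0:
            continue
        best = candidates[np.argmax(ious[r, candidates])]
        taken[best] = True
        is_tp[det_idx[r]] = True
        matched[annot_idx[best]] = True


def match_detections(
    dets: Sequence[Detection],
    annots: Sequence[Annotation],
    iou_threshold: float = 0.5,
    conf_threshold: float = 0.5,
    num_classes: int | None = None,
) -> MatchResult:
    """VOC-style TP/FP/FN matching at an operating confidence threshold."""
    if num_classes is not None:
        for d in dets:
            if not (0 <= d.class_id < num_classes):
                raise ValueError(f"detection class id {d.class_id} outside [0,{num_classes})")
        for a in annots:
            if not (0 <= a.class_id < num_classes):
                raise ValueError(f"annotation class id {a.class_id} outside [0,{num_classes})")
    keep = [i for i, d in enumerate(dets) if d.confidence >= conf_threshold]
    is_tp = np.zeros(len(dets), dtype=bool)
    matched = np.zeros(len(annots), dtype=bool)
    groups: dict[tuple[Hashable, int], tuple[list[int], list[int]]] = {}
    for i in keep:
        groups.setdefault((dets[i].image_id, dets[i].class_id), ([], []))[0].append(i)
    for j, a in enumerate(annots):
        groups.setdefault((a.image_id, a.class_id), ([], []))[1].append(j)
    for (_, _), (di, aj) in groups.items():
        if di:
            _greedy_match(dets, di, annots, aj, iou_threshold, is_tp, matched)
    class_counts: dict[int, tuple[int, int, int]] = {}
    classes = {dets[i].class_id for i in keep} | {a.class_id for a in annots}
    for c in sorted(classes):
        tp = sum(1 for i in keep if dets[i].class_id == c and is_tp[i])
        fp = sum(1 for i in keep if dets[i].class_id == c and not is_tp[i])
        fn = sum(1 for j, a in enumerate(annots) if a.class_id == c and not matched[j])
        class_counts[c] = (tp, fp, fn)
    return MatchResult(
        det_indices=np.array(keep, dtype=int),
        det_is_tp=is_tp[keep],
        annot_matched=matched,
        class_counts=class_counts,
    )


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """Pooled precision TP/(TP+FP) and recall TP/(TP+FN); 0 when undefined."""
    tp, fp, fn = m.tp, m.fp, m.fn
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return precision, recall


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def average_precision(
    dets: Sequence[Detection],
    annots: Sequence[Annotation],
    iou_threshold: float = 0.5,
    interpolation: str = "all_point",
) -> float:
    """Single-class AP: area under the interpolated precision envelope.

    All detections are ranked by descending confidence (stable in input
    order) with no confidence floor; matching is greedy in rank order within
    each image.  ``interpolation`` is ``"all_point"`` (continuous envelope,
    the default) or ``"11_point"`` (mean of the envelope at recalls
    0, 0.1, ..., 1).  Returns NaN when there are no annotations.
    """
    classes = {d.class_id for d in dets} | {a.class_id for a in annots}
    if len(classes) > 1:
        raise ValueError(f"average_precision is per-class; got class ids {sorted(classes)}")
    if not annots:
        warnings.warn("AP undefined for a class with zero annotations")
        return float("nan")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    is_tp = np.zeros(len(dets), dtype=bool)
    matched = np.zeros(len(annots), dtype=bool)
    by_image: dict[Hashable, list[int]] = {}
    for j, a in enumerate(annots):
        by_image.setdefault(a.image_id, []).append(j)
    for i in order:
        aj = by_image.get(dets[i].image_id, [])
        free = [j for j in aj if not matched[j]]
        if not free:
            continue
        ious = pairwise_iou(
            np.array([dets[i].box.as_tuple()]),
            np.array([annots[j].box.as_tuple() for j in free]),
        )[0]
        best = int(np.argmax(ious))
        if ious[best] >= iou_threshold:
            matched[free[best]] = True
            is_tp[i] = True
    flags = is_tp[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / len(annots)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    if interpolation == "11_point":
        ap = 0.0
        for r in np.linspace(0.0, 1.0, 11):
            mask = recall >= r
            ap += precision[mask].max() if mask.any() else 0.0
        return float(ap / 11.0)
    if interpolation != "all_point":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    # precision envelope, integrated over recall
    mrec = np.concatenate(([0.0], recall))
    mpre = np.concatenate(([0.0], precision))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    return float(np.sum(np.diff(mrec) * mpre[1:]))


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class AP plus precision/recall/F1 at the operating threshold."""

    class_id: int
    ap: float
    precision: float
    recall: float
    f1: float
    n_annotations: int


def evaluate_detections(
    dets: Sequence[Detection],
    annots: Sequence[Annotation],
    num_classes: int,
    iou_threshold: float = 0.5,
    conf_threshold: float = 0.5,
    interpolation: str = "all_point",
) -> list[ClassMetrics]:
    """Per-class metrics under the standard protocol.

    AP ranks all detections of the class with no confidence floor; precision,
    recall and F1 are computed at ``conf_threshold``.
    """
    match = match_detections(dets, annots, iou_threshold, conf_threshold, num_classes)
    out: list[ClassMetrics] = []
    for c in range(num_classes):
        c_dets = [d for d in dets if d.class_id == c]
        c_annots = [a for a in annots if a.class_id == c]
        if not c_dets and not c_annots:
            continue
        ap = average_precision(c_dets, c_annots, iou_threshold, interpolation)
        tp, fp, fn = match.class_counts.get(c, (0, 0, 0))
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        out.append(
            ClassMetrics(
                class_id=c,
                ap=ap,
                precision=precision,
                recall=recall,
                f1=f1_score(precision, recall),
                n_annotations=len(c_annots),
            )
        )
    return out


def summarize(per_class: Sequence[ClassMetrics]) -> dict[str, float]:
    """Unweighted macro means over classes: mAP, mPrecision, mRecall, mF1.

    Classes whose AP is undefined (no annotations) are excluded from mAP.
    """
    if not per_class:
        raise ValueError("summarize needs at least one class with metrics")
    aps = [m.ap for m in per_class if not math.isnan(m.ap)]
    if len(aps) < len(per_class):
        warnings.warn(
            f"{len(per_class) - len(aps)} class(es) with zero annotations excluded from mAP"
        )
    if not aps:
        raise ValueError("no class has a defined AP")
    return {
        "mAP": float(np.mean(aps)),
        "mPrecision": float(np.mean([m.precision for m in per_class])),
        "mRecall": float(np.mean([m.recall for m in per_class])),
        "mF1": float(np.mean([m.f1 for m in per_class])),
    }


@dataclass
class CountingReport:
    """Per-image counting comparison: RMSE, R^2 against the true counts, the
    OLS regression of predicted on true counts, and a signed-error histogram
    with unit-width integer bins."""

    pairs: list[tuple[int, int]]  # (N_g, N_p) per image
    rmse: float
    r2: float | None
    slope: float | None
    intercept: float | None
    hist_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    hist_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_images(self) -> int:
        return len(self.pairs)


def counting_pairs(
    dets: Sequence[Detection],
    truth_counts: dict[Hashable, int],
    conf_threshold: float = 0.5,
) -> list[tuple[int, int]]:
    """Build per-image (true count, predicted count) pairs.

    ``truth_counts`` maps every evaluated image id to its ground-truth object
    count; the predicted count pools retained detections of all classes with
    confidence at or above the threshold.
    """
    pred: dict[Hashable, int] = {k: 0 for k in truth_counts}
    for d in dets:
        if d.confidence >= conf_threshold and d.image_id in pred:
            pred[d.image_id] += 1
    return [(int(truth_counts[k]), pred[k]) for k in truth_counts]


def counting_metrics(pairs: Sequence[tuple[int, int]]) -> CountingReport:
    """Counting statistics over per-image (N_g, N_p) pairs.

    RMSE is computed for any k >= 1; R^2 and the regression line need k >= 2
    and are None below that.  R^2 is 1 minus the ratio of squared prediction
    error to squared deviation of the true counts from their mean (1.0 when
    both are zero, i.e. constant truth predicted exactly).
    """
    if not pairs:
        raise ValueError("counting_metrics needs at least one image")
    ng = np.array([p[0] for p in pairs], dtype=float)
    np_ = np.array([p[1] for p in pairs], dtype=float)
    if np.any(ng < 0) or np.any(np_ < 0):
        raise ValueError("counts must be non-negative")
    errors = np_ - ng
    rmse = float(np.sqrt(np.mean(errors**2)))
    r2 = slope = intercept = None
    if len(pairs) >= 2:
        ss_res = float(np.sum((np_ - ng) ** 2))
        ss_tot = float(np.sum((ng - ng.mean()) ** 2))
        if ss_tot > 0:
            r2 = 1.0 - ss_res / ss_tot
        else:
            r2 = 1.0 if ss_res == 0.0 else None
        if ss_tot > 0:
            slope_, intercept_ = np.polyfit(ng, np_, 1)
            slope, intercept = float(slope_), float(intercept_)
    lo = int(np.floor(errors.min()))
    hi = int(np.ceil(errors.max()))
    edges = np.arange(lo - 0.5, hi + 1.5)
    counts, _ = np.histogram(errors, bins=edges)
    return CountingReport(
        pairs=[(int(a), int(b)) for a, b in pairs],
        rmse=rmse,
        r2=r2,
        slope=slope,
        intercept=intercept,
        hist_edges=edges,
        hist_counts=counts,
    )
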