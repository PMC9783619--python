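"""Bounding-box selection and suppression for dense tiny-object scenes.

Implements the confluence strategy — a non-IoU, Manhattan-proximity-based
two-stage selection/removal algorithm — together with greedy NMS and
DIoU-NMS baselines for comparison.

Confluence in brief
-------------------
For a pair of boxes, their coordinates are jointly min-max normalized to
[0, 1] per axis and the proximity ``P`` is the L1 distance between the two
top-left corners plus the L1 distance between the two bottom-right corners.
Two boxes are *confluent* when ``P`` falls below a threshold (2 by default):
they are considered to describe the same object.  Within a cluster of
confluent boxes the retained box is the one with the smallest weighted
proximity ``WP = P / c`` where ``c`` is the confidence — the division
biases retention toward high-confidence boxes.  Boxes with confidence
below 0.05 are discarded before clustering.

The selection loop is: repeat until no confluent pairs remain —
(i) every box with no confluent partner is retained outright;
(ii) each remaining box's WP is its smallest P over current confluent
neighbours divided by its confidence; (iii) the globally minimal-WP box is
retained and every box with ``P < removal_threshold`` to it is removed.
Ties on WP go to the higher confidence, then to the earlier input index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset_io import (  # noqa: F401  (re-exported: the detections table is this module's interface)
    read_detections_csv,
    read_detections_jsonl,
    write_detections_csv,
    write_detections_jsonl,
)
from .geometry import Box, Detection

__all__ = [
    "SuppressionConfig",
    "ProximityRecord",
    "normalize_pair",
    "proximity",
    "weighted_proximity",
    "confluence",
    "nms",
    "diou_nms",
    "suppress",
    "read_detections_csv",
    "write_detections_csv",
    "read_detections_jsonl",
    "write_detections_jsonl",
]


@dataclass(frozen=True)
class SuppressionConfig:
    """Thresholds for confluence and the NMS baselines.

    ``proximity_threshold``: pairs with P below this are confluent (default 2).
    ``confidence_floor``: boxes with confidence below this are discarded first
    (default 0.05).  ``removal_threshold`` defaults to the proximity threshold.
    ``iou_threshold`` only affects the NMS/DIoU-NMS baselines.
    """

    proximity_threshold: float = 2.0
    confidence_floor: float = 0.05
    class_aware: bool = True
    removal_threshold: float | None = None
    iou_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.proximity_threshold <= 4.0):
            raise ValueError(f"proximity_threshold must be in (0,4], got {self.proximity_threshold}")
        if not (0.0 <= self.confidence_floor < 1.0):
            raise ValueError(f"confidence_floor must be in [0,1), got {self.confidence_floor}")
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError(f"iou_threshold must be in (0,1), got {self.iou_threshold}")
        if self.removal_threshold is not None and self.removal_threshold <= 0.0:
            raise ValueError("removal_threshold must be positive")

    @property
    def effective_removal_threshold(self) -> float:
        return self.proximity_threshold if self.removal_threshold is None else self.removal_threshold


@dataclass(frozen=True)
class ProximityRecord:
    """Proximity bookkeeping for one pair of detections."""

    index_a: int
    index_b: int
    P: float
    WP_a: float
    WP_b: float

    def confluent(self, threshold: float = 2.0) -> bool:
        return self.P < threshold


def normalize_pair(a: Box, b: Box) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Jointly min-max scale a pair of boxes to [0, 1] per axis.

    The four x coordinates of the pair are scaled together, and likewise the
    four y coordinates, preserving the boxes' relative geometry.  A zero span
    (possible only for coincident degenerate input, kept for API robustness)
    maps that axis to all zeros.  Returns two coordinate 4-tuples — the
    normalized shapes may be degenerate, so they are not ``Box`` instances.
    """
    xs = (a.x1, a.x2, b.x1, b.x2)
    ys = (a.y1, a.y2, b.y1, b.y2)
    x_min, x_span = min(xs), max(xs) - min(xs)
    y_min, y_span = min(ys), max(ys) - min(ys)

    def nx(v: float) -> float:
        return (v - x_min) / x_span if x_span > 0.0 else 0.0

    def ny(v: float) -> float:
        return (v - y_min) / y_span if y_span > 0.0 else 0.0

    return (
        (nx(a.x1), ny(a.y1), nx(a.x2), ny(a.y2)),
        (nx(b.x1), ny(b.y1), nx(b.x2), ny(b.y2)),
    )


def proximity(a: Box, b: Box) -> float:
    """Manhattan proximity P between two boxes after joint normalization.

    P is the L1 distance between the normalized top-left corners plus the L1
    distance between the normalized bottom-right corners; symmetric, zero iff
    the boxes coincide, and bounded by 4.
    """
    na, nb = normalize_pair(a, b)
    return abs(na[0] - nb[0]) + abs(na[1] - nb[1]) + abs(na[2] - nb[2]) + abs(na[3] - nb[3])


def weighted_proximity(P: float, c: float) -> float:
    """Confidence-weighted proximity WP = P / c.

    Dividing by the confidence biases selection toward high-confidence boxes:
    for a fixed P, a more confident box has a smaller WP and is preferred.
    """
    if c <= 0.0:
        raise ValueError(f"confidence must be positive for weighted proximity, got {c}")
    return P / c


def _proximity_matrix(boxes: np.ndarray) -> np.ndarray:
    """Pairwise P for an (N,4) corner-box array.

    Because the joint min over the x (resp. y) values of a valid pair always
    spans at least one box's width (resp. height), the span is strictly
    positive and the normalized corner differences reduce to the raw
    differences divided by the pair's span.
    """
    x1, y1, x2, y2 = boxes[:, 0], boxes[:, 1], boxes[:, 2], boxes[:, 3]
    span_x = np.maximum.outer(x2, x2) - np.minimum.outer(x1, x1)
    span_y = np.maximum.outer(y2, y2) - np.minimum.outer(y1, y1)
    px = (np.abs(x1[:, None] - x1[None, :]) + np.abs(x2[:, None] - x2[None, :])) / span_x
    py = (np.abs(y1[:, None] - y1[None, :]) + np.abs(y2[:, None] - y2[None, :])) / span_y
    return px + py


def _require_single_image(dets: Sequence[Detection]) -> None:
    ids = {d.image_id for d in dets}
    if len(ids) > 1:
        raise ValueError(f"suppression operates on one image at a time; got image ids {sorted(map(str, ids))}")


def _confluence_indices(
    boxes: np.ndarray, confs: np.ndarray, cfg: SuppressionConfig
) -> list[int]:
    """Run the confluence selection loop on one class group; returns kept row indices."""
    n = len(confs)
    if n == 1:
        return [0]
    P = _proximity_matrix(boxes)
    thr = cfg.proximity_threshold
    rem = cfg.effective_removal_threshold
    alive = np.ones(n, dtype=bool)
    kept: list[int] = []
    while alive.any():
        adj = (P < thr) & alive[None, :] & alive[:, None]
        np.fill_diagonal(adj, False)
        degree = adj.sum(axis=1)
        lonely = alive & (degree == 0)
        kept.extend(np.flatnonzero(lonely).tolist())
        alive[lonely] = False
        engaged = np.flatnonzero(alive)
        if engaged.size == 0:
            break
        best_key: tuple[float, float, int] | None = None
        best_i = -1
        for i in engaged:
            min_p = P[i, adj[i]].min()
            key = (min_p / confs[i], -confs[i], i)
            if best_key is None or key < best_key:
                best_key, best_i = key, int(i)
        kept.append(best_i)
        alive[best_i] = False
        alive[alive & (P[best_i] < rem)] = False
    return sorted(kept)


def confluence(dets: Sequence[Detection], cfg: SuppressionConfig | None = None) -> list[Detection]:
    """Confluence bounding-box selection on one image's detections.

    Discards boxes below the confidence floor, then runs the two-stage
    retain/remove loop per class (or on all classes pooled when
    ``cfg.class_aware`` is false).  Returns the retained subset in input order.
    """
    cfg = cfg or SuppressionConfig()
    _require_single_image(dets)
    indexed = [(i, d) for i, d in enumerate(dets) if d.confidence >= cfg.confidence_floor]
    if not indexed:
        return []
    groups: dict[int, list[tuple[int, Detection]]] = {}
    for i, d in indexed:
        groups.setdefault(d.class_id if cfg.class_aware else 0, []).append((i, d))
    kept_orig: list[int] = []
    for _, members in sorted(groups.items()):
        boxes = np.array([d.box.as_tuple() for _, d in members], dtype=float)
        confs = np.array([d.confidence for _, d in members], dtype=float)
        for row in _confluence_indices(boxes, confs, cfg):
            kept_orig.append(members[row][0])
    return [dets[i] for i in sorted(kept_orig)]


def _greedy_nms(
    dets: Sequence[Detection],
    iou_threshold: float,
    class_aware: bool,
    diou: bool,
) -> list[Detection]:
    from .geometry import diou_penalty, iou as box_iou

    _require_single_image(dets)
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    kept: list[int] = []
    for i in order:
        suppressed = False
        for j in kept:
            if class_aware and dets[i].class_id != dets[j].class_id:
                continue
            overlap = box_iou(dets[j].box, dets[i].box)
            if diou:
                overlap -= diou_penalty(dets[j].box, dets[i].box)
            if overlap > iou_threshold:
                suppressed = True
                break
        if not suppressed:
            kept.append(i)
    return [dets[i] for i in sorted(kept)]


def nms(
    dets: Sequence[Detection], iou_threshold: float = 0.5, class_aware: bool = True
) -> list[Detection]:
    """Greedy non-maximum suppression: descending-confidence selection, ties
    broken by input order; a candidate is dropped when its IoU with an
    already-kept box exceeds the threshold."""
    return _greedy_nms(dets, iou_threshold, class_aware, diou=False)


def diou_nms(
    dets: Sequence[Detection], iou_threshold: float = 0.5, class_aware: bool = True
) -> list[Detection]:
    """DIoU-NMS baseline: as :func:`nms` but the suppression criterion is
    ``IoU - center-distance penalty > threshold``, which spares overlapping
    boxes whose centers are far apart."""
    return _greedy_nms(dets, iou_threshold, class_aware, diou=True)


def suppress(
    dets: Sequence[Detection], method: str, cfg: SuppressionConfig | None = None
) -> list[Detection]:
    """Dispatch by method name: ``confluence``, ``nms`` or ``diou-nms``.

    Detections may span several images; each image is processed independently.
    """
    cfg = cfg or SuppressionConfig()
    by_image: dict = {}
    order: list = []
    for d in dets:
        if d.image_id not in by_image:
            by_image[d.image_id] = []
            order.append(d.image_id)
        by_image[d.image_id].append(d)
    out: list[Detection] = []
    for image_id in order:
        group = by_image[image_id]
        if method == "confluence":
            out.extend(confluence(group, cfg))
        elif method == "nms":
            out.extend(nms(group, cfg.iou_threshold, cfg.class_aware))
        elif method == "diou-nms":
            out.extend(diou_nms(group, cfg.iou_threshold, cfg.class_aware))
        else:
            raise ValueError(f"unknown suppression method {method!r}; expected confluence, nms or diou-nms")
    return out
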