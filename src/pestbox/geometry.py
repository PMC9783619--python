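"""Axis-aligned box geometry and overlap/penalty measures.

Conventions
-----------
Coordinates are continuous, with the origin at the top-left corner of the
image, x increasing rightward and y downward.  Boxes are stored in corner
form ``(x1, y1, x2, y2)`` with ``x2 > x1`` and ``y2 > y1``, so areas are
geometric (``(x2-x1)*(y2-y1)``), not pixel-index counts.  Zero-area boxes
are rejected at construction: downstream overlap measures never have to
define behaviour for them.

PASCAL VOC XML stores 1-based inclusive pixel indices; :mod:`pestbox.dataset_io`
converts those to this half-open geometric convention on read
(``x1 = xmin - 1``, ``x2 = xmax``), so a one-pixel object has area 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable

import numpy as np

__all__ = [
    "Box",
    "ImageSize",
    "Detection",
    "Annotation",
    "iou",
    "pairwise_iou",
    "diou_penalty",
    "ciou_loss",
    "ciou_loss_many",
    "relative_scale",
]


@dataclass(frozen=True, slots=True)
class Box:
    """Axis-aligned box in corner form; strictly positive width and height."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x2 > self.x1):
            raise ValueError(f"degenerate box: x2={self.x2} must exceed x1={self.x1}")
        if not (self.y2 > self.y1):
            raise ValueError(f"degenerate box: y2={self.y2} must exceed y1={self.y1}")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


@dataclass(frozen=True, slots=True)
class ImageSize:
    """Image extent in pixels."""

    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"image size must be >= 1x1, got {self.width}x{self.height}")

    @property
    def area(self) -> float:
        return float(self.width) * float(self.height)


@dataclass(frozen=True, slots=True)
class Detection:
    """A detector output: a scored, classified box on one image."""

    image_id: Hashable
    class_id: int
    box: Box
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0,1], got {self.confidence}")


@dataclass(frozen=True, slots=True)
class Annotation:
    """A ground-truth box with its class on one image."""

    image_id: Hashable
    class_id: int
    box: Box


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1]."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between two arrays of corner boxes, shapes (N,4) and (M,4)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0.0, None) * np.clip(iy, 0.0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


def diou_penalty(a: Box, b: Box) -> float:
    """Normalized center-distance penalty: squared center distance over the
    squared diagonal of the smallest enclosing box.  Zero iff centers coincide;
    always <= 1."""
    (ax, ay), (bx, by) = a.center, b.center
    d2 = (ax - bx) ** 2 + (ay - by) ** 2
    cw = max(a.x2, b.x2) - min(a.x1, b.x1)
    ch = max(a.y2, b.y2) - min(a.y1, b.y1)
    return d2 / (cw * cw + ch * ch)


def ciou_loss(pred: Box, gt: Box) -> float:
    """Complete-IoU regression loss: 1 - IoU + center-distance penalty + an
    aspect-ratio consistency term.  Zero iff the boxes are identical."""
    j = iou(pred, gt)
    v = (4.0 / math.pi**2) * (
        math.atan(gt.width / gt.height) - math.atan(pred.width / pred.height)
    ) ** 2
    denom = (1.0 - j) + v
    alpha_v = v / denom if denom > 0.0 else 0.0
    return 1.0 - j + diou_penalty(pred, gt) + alpha_v * v


def ciou_loss_many(pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Elementwise CIoU loss between aligned arrays of corner boxes, shape (...,4).

    Pure elementwise arithmetic, so it lifts unchanged onto autodiff array types.
    """
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    ix = np.minimum(pred[..., 2], gt[..., 2]) - np.maximum(pred[..., 0], gt[..., 0])
    iy = np.minimum(pred[..., 3], gt[..., 3]) - np.maximum(pred[..., 1], gt[..., 1])
    inter = np.clip(ix, 0.0, None) * np.clip(iy, 0.0, None)
    wp = pred[..., 2] - pred[..., 0]
    hp = pred[..., 3] - pred[..., 1]
    wg = gt[..., 2] - gt[..., 0]
    hg = gt[..., 3] - gt[..., 1]
    j = inter / (wp * hp + wg * hg - inter)

    cxp = 0.5 * (pred[..., 0] + pred[..., 2])
    cyp = 0.5 * (pred[..., 1] + pred[..., 3])
    cxg = 0.5 * (gt[..., 0] + gt[..., 2])
    cyg = 0.5 * (gt[..., 1] + gt[..., 3])
    cw = np.maximum(pred[..., 2], gt[..., 2]) - np.minimum(pred[..., 0], gt[..., 0])
    ch = np.maximum(pred[..., 3], gt[..., 3]) - np.minimum(pred[..., 1], gt[..., 1])
    penalty = ((cxp - cxg) ** 2 + (cyp - cyg) ** 2) / (cw**2 + ch**2)

    v = (4.0 / math.pi**2) * (np.arctan(wg / hg) - np.arctan(wp / hp)) ** 2
    denom = (1.0 - j) + v
    alpha_v = np.where(denom > 0.0, v / np.where(denom > 0.0, denom, 1.0), 0.0)
    return 1.0 - j + penalty + alpha_v * v


def relative_scale(box: Box, size: ImageSize) -> float:
    """Box area as a fraction of the image area.

    The trap-image regime of interest is extremely small objects: almost all
    annotations occupy less than 0.4% of the image.
    """
    for name, value, low, high in (
        ("x1", box.x1, 0.0, size.width),
        ("x2", box.x2, 0.0, size.width),
        ("y1", box.y1, 0.0, size.height),
        ("y2", box.y2, 0.0, size.height),
    ):
        if value < low or value > high:
            raise ValueError(
                f"box coordinate {name}={value} lies outside the {size.width}x{size.height} image"
            )
    return box.area / size.area
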