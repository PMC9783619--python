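"""Dataset plumbing: VOC XML annotations, detection tables, dataset splits,
minority-class augmentation, IoU-metric anchor clustering and the warm-up +
cosine-annealing learning-rate schedule.

File formats
------------
Ground truth is PASCAL VOC XML in the labelImg dialect
(``annotation/size``, ``annotation/object/name``, ``bndbox`` with 1-based
inclusive ``xmin/ymin/xmax/ymax``).  On read the pixel indices are mapped to
the half-open geometric convention of :mod:`pestbox.geometry`
(``x1 = xmin - 1``, ``x2 = xmax``), so a one-pixel object has area 1; writing
inverts the mapping.

Detections travel as a flat CSV (header
``image_id,class_id,x1,y1,x2,y2,confidence``, UTF-8, '.' decimal) or as a
JSONL mirror with identical field names.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .geometry import Annotation, Box, Detection, ImageSize
from .pest24 import PEST24_CLASS_NAMES, PEST24_MINORITY_CLASSES

__all__ = [
    "read_detections_csv",
    "write_detections_csv",
    "read_detections_jsonl",
    "write_detections_jsonl",
    "read_voc_xml",
    "write_voc_xml",
    "SplitSpec",
    "split_dataset",
    "AugmentationPlan",
    "augment",
    "AnchorSet",
    "DEFAULT_ANCHORS",
    "kmeans_anchors",
    "ScheduleConfig",
    "cosine_schedule",
    "schedule_curve",
]

DETECTION_COLUMNS = ("image_id", "class_id", "x1", "y1", "x2", "y2", "confidence")


# ---------------------------------------------------------------------------
# detection tables


def _detections_to_frame(dets: Iterable[Detection]) -> pd.DataFrame:
    rows = [
        (d.image_id, d.class_id, d.box.x1, d.box.y1, d.box.x2, d.box.y2, d.confidence)
        for d in dets
    ]
    return pd.DataFrame(rows, columns=list(DETECTION_COLUMNS))


def _frame_to_detections(frame: pd.DataFrame, source: str) -> list[Detection]:
    missing = set(DETECTION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{source}: missing detection columns {sorted(missing)}")
    return [
        Detection(
            image_id=str(r.image_id),
            class_id=int(r.class_id),
            box=Box(float(r.x1), float(r.y1), float(r.x2), float(r.y2)),
            confidence=float(r.confidence),
        )
        for r in frame.itertuples(index=False)
    ]


def write_detections_csv(path: str | Path, dets: Iterable[Detection]) -> None:
    # %.17g round-trips IEEE doubles exactly
    _detections_to_frame(dets).to_csv(path, index=False, float_format="%.17g")


def read_detections_csv(path: str | Path) -> list[Detection]:
    frame = pd.read_csv(path, dtype={"image_id": str}, float_precision="round_trip")
    return _frame_to_detections(frame, str(path))


def write_detections_jsonl(path: str | Path, dets: Iterable[Detection]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in dets:
            fh.write(
                json.dumps(
                    {
                        "image_id": d.image_id,
                        "class_id": d.class_id,
                        "x1": d.box.x1,
                        "y1": d.box.y1,
                        "x2": d.box.x2,
                        "y2": d.box.y2,
                        "confidence": d.confidence,
                    }
                )
                + "\n"
            )


def read_detections_jsonl(path: str | Path) -> list[Detection]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                records.append(json.loads(line))
    return _frame_to_detections(pd.DataFrame(records), str(path))


# ---------------------------------------------------------------------------
# VOC XML


def read_voc_xml(
    path: str | Path, class_names: Sequence[str] = PEST24_CLASS_NAMES
) -> tuple[ImageSize, list[Annotation]]:
    """Parse one labelImg-dialect VOC XML file.

    Returns the image size and the annotations with coordinates converted to
    the geometric convention.  Unknown class names, inverted boxes and
    malformed XML raise errors naming the file (and object index).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed VOC XML ({exc})") from exc
    root = tree.getroot()
    size_el = root.find("size")
    if size_el is None:
        raise ValueError(f"{path}: missing <size> element")
    size = ImageSize(int(size_el.findtext("width")), int(size_el.findtext("height")))
    filename = root.findtext("filename") or path.name
    image_id = Path(filename).stem
    name_to_id = {name: i for i, name in enumerate(class_names)}
    annots: list[Annotation] = []
    for idx, obj in enumerate(root.findall("object")):
        name = obj.findtext("name")
        if name not in name_to_id:
            raise ValueError(f"{path}: object {idx} has unknown class name {name!r}")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"{path}: object {idx} has no <bndbox>")
        xmin = float(bnd.findtext("xmin"))
        ymin = float(bnd.findtext("ymin"))
        xmax = float(bnd.findtext("xmax"))
        ymax = float(bnd.findtext("ymax"))
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(
                f"{path}: object {idx} has inverted box (xmin={xmin}, ymin={ymin}, xmax={xmax}, ymax={ymax})"
            )
        annots.append(
            Annotation(
                image_id=image_id,
                class_id=name_to_id[name],
                box=Box(xmin - 1.0, ymin - 1.0, xmax, ymax),
            )
        )
    return size, annots


def write_voc_xml(
    path: str | Path,
    size: ImageSize,
    annotations: Sequence[Annotation],
    class_names: Sequence[str] = PEST24_CLASS_NAMES,
    image_id: str | None = None,
) -> None:
    """Write annotations as labelImg-dialect VOC XML (inverse of :func:`read_voc_xml`)."""
    if image_id is None:
        image_id = str(annotations[0].image_id) if annotations else Path(path).stem
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = f"{image_id}.jpg"
    size_el = etree.SubElement(root, "size")
    etree.SubElement(size_el, "width").text = str(size.width)
    etree.SubElement(size_el, "height").text = str(size.height)
    etree.SubElement(size_el, "depth").text = "3"
    for a in annotations:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = class_names[a.class_id]
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(round(a.box.x1)) + 1)
        etree.SubElement(bnd, "ymin").text = str(int(round(a.box.y1)) + 1)
        etree.SubElement(bnd, "xmax").text = str(int(round(a.box.x2)))
        etree.SubElement(bnd, "ymax").text = str(int(round(a.box.y2)))
    etree.ElementTree(root).write(str(path), pretty_print=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# splits


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test ratios with a shuffle seed (default 70/20/10)."""

    ratios: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError(f"split ratios must be positive, got {self.ratios}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.ratios}")


def split_dataset(
    image_ids: Sequence, spec: SplitSpec | None = None
) -> tuple[list, list, list]:
    """Seeded random partition into train/val/test.

    Subset sizes are the largest-remainder rounding of the ratios, so they
    always sum to the input size (ties go to the earlier subset).
    """
    spec = spec or SplitSpec()
    n = len(image_ids)
    if n < 3:
        raise ValueError(f"need at least 3 ids to split, got {n}")
    exact = [n * r for r in spec.ratios]
    sizes = [math.floor(e) for e in exact]
    remainder = n - sum(sizes)
    by_frac = sorted(range(3), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in by_frac[:remainder]:
        sizes[i] += 1
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    shuffled = [image_ids[i] for i in order]
    train = shuffled[: sizes[0]]
    val = shuffled[sizes[0] : sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1] :]
    return train, val, test


# ---------------------------------------------------------------------------
# augmentation

TRANSFORM_NAMES = ("hflip", "vflip", "hue", "rotate", "affine")


@dataclass(frozen=True)
class AugmentationPlan:
    """Augmentation recipe for minority classes.

    Only images containing at least one target class are augmented; each
    eligible image yields ``variants_per_image`` variants, each built from a
    random non-empty combination of the five supported transforms with random
    parameters.  Geometric parameter ranges are deliberately mild: trap
    images are top-down, so small rotations and near-identity affines cover
    the realistic pose variation.
    """

    target_classes: frozenset[int] = frozenset(PEST24_MINORITY_CLASSES)
    transforms: tuple[str, ...] = TRANSFORM_NAMES
    variants_per_image: int = 5
    rotation_range: float = 15.0  # degrees, +/-
    shear_range: float = 0.1  # radians, +/-
    scale_range: tuple[float, float] = (0.9, 1.1)
    hue_shift_range: float = 0.1  # fraction of the hue circle, +/-
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.transforms) - set(TRANSFORM_NAMES)
        if unknown:
            raise ValueError(f"unknown transforms {sorted(unknown)}; supported: {TRANSFORM_NAMES}")


def _map_boxes(tform, boxes: Sequence[Box], width: float, height: float) -> list[Box | None]:
    """Axis-aligned hull of each box's transformed corners, clipped to the
    image; boxes whose clipped area falls below one pixel are dropped (None)."""
    out: list[Box | None] = []
    for b in boxes:
        corners = np.array(
            [[b.x1, b.y1], [b.x2, b.y1], [b.x1, b.y2], [b.x2, b.y2]], dtype=float
        )
        mapped = tform(corners)
        x1 = float(np.clip(mapped[:, 0].min(), 0.0, width))
        x2 = float(np.clip(mapped[:, 0].max(), 0.0, width))
        y1 = float(np.clip(mapped[:, 1].min(), 0.0, height))
        y2 = float(np.clip(mapped[:, 1].max(), 0.0, height))
        if (x2 - x1) * (y2 - y1) < 1.0:
            out.append(None)
        else:
            out.append(Box(x1, y1, x2, y2))
    return out


def _apply_transform(
    name: str,
    image: np.ndarray,
    boxes: list[Box | None],
    plan: AugmentationPlan,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[Box | None]]:
    from skimage import transform as sktf
    from skimage.color import hsv2rgb, rgb2hsv

    height, width = image.shape[:2]
    live = [b for b in boxes if b is not None]
    if name == "hflip":
        image = image[:, ::-1].copy()
        boxes = [Box(width - b.x2, b.y1, width - b.x1, b.y2) if b else None for b in boxes]
    elif name == "vflip":
        image = image[::-1, :].copy()
        boxes = [Box(b.x1, height - b.y2, b.x2, height - b.y1) if b else None for b in boxes]
    elif name == "hue":
        if image.ndim == 3 and image.shape[2] == 3:
            shift = rng.uniform(-plan.hue_shift_range, plan.hue_shift_range)
            hsv = rgb2hsv(image)
            hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
            image = hsv2rgb(hsv)
        # grayscale images carry no hue; boxes are unchanged either way
    elif name in ("rotate", "affine"):
        center = np.array([width / 2.0, height / 2.0])
        if name == "rotate":
            angle = math.radians(rng.uniform(-plan.rotation_range, plan.rotation_range))
            core = sktf.AffineTransform(rotation=angle)
        else:
            sx = rng.uniform(*plan.scale_range)
            sy = rng.uniform(*plan.scale_range)
            shear = rng.uniform(-plan.shear_range, plan.shear_range)
            core = sktf.AffineTransform(scale=(sx, sy), shear=shear)
        tform = (
            sktf.SimilarityTransform(translation=-center)
            + core
            + sktf.SimilarityTransform(translation=center)
        )
        image = sktf.warp(image, tform.inverse, order=1, mode="constant", preserve_range=True)
        mapped = _map_boxes(tform, live, width, height)
        it = iter(mapped)
        boxes = [next(it) if b is not None else None for b in boxes]
    return image, boxes


def augment(
    image: np.ndarray,
    annots: Sequence[Annotation],
    plan: AugmentationPlan | None = None,
) -> list[tuple[np.ndarray, list[Annotation]]]:
    """Generate augmented variants of one image and its annotations.

    Returns an empty list when the image contains none of the plan's target
    classes.  Variants whose annotation set becomes empty (all boxes pushed
    out of frame) are dropped with a warning.  Images are handled as float
    arrays in [0, 1] (uint8 inputs are rescaled).
    """
    from skimage.util import img_as_float

    plan = plan or AugmentationPlan()
    if not any(a.class_id in plan.target_classes for a in annots):
        return []
    rng = np.random.default_rng(plan.seed)
    base = img_as_float(np.asarray(image))
    variants: list[tuple[np.ndarray, list[Annotation]]] = []
    for _ in range(plan.variants_per_image):
        k = int(rng.integers(1, len(plan.transforms) + 1))
        chosen_idx = sorted(rng.choice(len(plan.transforms), size=k, replace=False).tolist())
        img = base.copy()
        boxes: list[Box | None] = [a.box for a in annots]
        for ti in chosen_idx:
            img, boxes = _apply_transform(plan.transforms[ti], img, boxes, plan, rng)
        new_annots = [
            Annotation(image_id=a.image_id, class_id=a.class_id, box=b)
            for a, b in zip(annots, boxes)
            if b is not None
        ]
        if annots and not new_annots:
            warnings.warn("augmentation variant dropped: every box left the frame")
            continue
        variants.append((img, new_annots))
    return variants


# ---------------------------------------------------------------------------
# anchor clustering

#: Stock multi-scale anchor priors for 416x416 input (width, height), area
#: ascending; :func:`kmeans_anchors` regenerates anchors for other data.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (12, 16), (19, 36), (40, 28), (36, 75), (76, 55),
    (72, 146), (142, 110), (192, 243), (459, 401),
)


@dataclass(frozen=True)
class AnchorSet:
    """k anchor (width, height) centroids, sorted by area ascending."""

    anchors: tuple[tuple[float, float], ...]
    mean_iou: float | None = None

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("an AnchorSet needs at least one anchor")
        if any(w <= 0 or h <= 0 for w, h in self.anchors):
            raise ValueError("anchor dimensions must be positive")

    def __len__(self) -> int:
        return len(self.anchors)

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("width,height\n")
            for w, h in self.anchors:
                fh.write(f"{w},{h}\n")

    @classmethod
    def load_csv(cls, path: str | Path) -> "AnchorSet":
        frame = pd.read_csv(path)
        return cls(tuple((float(r.width), float(r.height)) for r in frame.itertuples(index=False)))


def _wh_iou(wh: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """IoU between co-centered (w,h) pairs, shapes (N,2) x (K,2) -> (N,K)."""
    inter = np.minimum(wh[:, None, 0], centers[None, :, 0]) * np.minimum(
        wh[:, None, 1], centers[None, :, 1]
    )
    union = wh[:, 0][:, None] * wh[:, 1][:, None] + centers[:, 0] * centers[:, 1] - inter
    return inter / union


def _kmeans_iou(
    wh: np.ndarray,
    k: int,
    rng: np.random.Generator,
    init_centers: np.ndarray | None = None,
    max_iter: int = 300,
) -> tuple[np.ndarray, list[float]]:
    """Lloyd iterations under the 1-IoU distance; returns (centers, objective history)."""
    if init_centers is None:
        distinct = np.unique(wh, axis=0)
        centers = [distinct[rng.integers(len(distinct))]]
        while len(centers) < k:
            d = 1.0 - _wh_iou(distinct, np.array(centers))
            d2 = d.min(axis=1) ** 2
            total = d2.sum()
            if total > 0:
                probs = d2 / total
                centers.append(distinct[rng.choice(len(distinct), p=probs)])
            else:  # all remaining points coincide with a center
                centers.append(distinct[rng.integers(len(distinct))])
        centers = np.array(centers, dtype=float)
    else:
        centers = np.asarray(init_centers, dtype=float).copy()
    assign = np.full(len(wh), -1)
    history: list[float] = []
    prev_centers = centers.copy()
    for _ in range(max_iter):
        d = 1.0 - _wh_iou(wh, centers)
        objective = float(d.min(axis=1).mean())
        if history and objective > history[-1] + 1e-12:
            # the mean update minimizes squared Euclidean, not 1-IoU, so it can
            # occasionally raise the objective: keep the better centers and stop
            centers = prev_centers
            break
        history.append(objective)
        new_assign = d.argmin(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        prev_centers = centers.copy()
        for j in range(k):
            members = wh[assign == j]
            if len(members) > 0:
                centers[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster at the worst-covered point
                centers[j] = wh[d.min(axis=1).argmax()]
    return centers, history


def kmeans_anchors(
    wh_pairs: Sequence[tuple[float, float]] | np.ndarray, k: int = 9, seed: int = 0
) -> AnchorSet:
    """Cluster ground-truth (width, height) pairs into k anchor priors.

    Uses Lloyd's algorithm under the detection-specific distance
    ``d = 1 - IoU(box, centroid)`` with boxes co-centered, seeded
    k-means++-style initialization on distinct pairs, and mean-update
    centroids.  The objective (mean 1-IoU to the nearest centroid) is
    non-increasing across iterations.
    """
    wh = np.asarray(wh_pairs, dtype=float)
    if wh.ndim != 2 or wh.shape[1] != 2:
        raise ValueError(f"wh_pairs must be an (N,2) array, got shape {wh.shape}")
    if np.any(wh <= 0):
        raise ValueError("anchor clustering requires strictly positive widths and heights")
    n_distinct = len(np.unique(wh, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct (w,h) pairs ({n_distinct})")
    rng = np.random.default_rng(seed)
    centers, history = _kmeans_iou(wh, k, rng)
    order = np.argsort(centers[:, 0] * centers[:, 1])
    anchors = tuple((float(w), float(h)) for w, h in centers[order])
    return AnchorSet(anchors=anchors, mean_iou=1.0 - history[-1])


# ---------------------------------------------------------------------------
# learning-rate schedule


@dataclass(frozen=True)
class ScheduleConfig:
    """Warm-up + plateau + cosine-annealing learning-rate schedule.

    Epochs ``[0, warmup)`` ramp linearly from ``lambda_min`` to
    ``lambda_max``; ``[warmup, warmup+plateau)`` hold ``lambda_max``; the
    remaining epochs decay along a half cosine from ``lambda_max`` at the
    start of the cosine phase to ``lambda_min`` at ``total_epochs``.
    ``t_cur`` is the global epoch at which the schedule is evaluated.
    """

    lambda_min: float = 1e-4
    lambda_max: float = 1e-3
    warmup_epochs: int = 5
    plateau_epochs: int = 5
    total_epochs: int = 200
    t_cur: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lambda_min < self.lambda_max):
            raise ValueError(
                f"need 0 < lambda_min < lambda_max, got {self.lambda_min}, {self.lambda_max}"
            )
        if self.warmup_epochs < 0 or self.plateau_epochs < 0:
            raise ValueError("phase lengths must be non-negative")
        if self.total_epochs <= self.warmup_epochs + self.plateau_epochs:
            raise ValueError("total_epochs must leave room for the cosine phase")

    @property
    def cosine_start(self) -> int:
        return self.warmup_epochs + self.plateau_epochs

    def at(self, epoch: int) -> float:
        """Learning rate at a global epoch in [0, total_epochs]."""
        if epoch < 0 or epoch > self.total_epochs:
            raise ValueError(f"epoch {epoch} outside [0, {self.total_epochs}]")
        if epoch < self.warmup_epochs:
            frac = epoch / self.warmup_epochs
            return self.lambda_min + (self.lambda_max - self.lambda_min) * frac
        if epoch < self.cosine_start:
            return self.lambda_max
        t = epoch - self.cosine_start
        t_i = self.total_epochs - self.cosine_start
        return self.lambda_min + 0.5 * (self.lambda_max - self.lambda_min) * (
            1.0 + math.cos(math.pi * t / t_i)
        )


def cosine_schedule(cfg: ScheduleConfig) -> float:
    """Learning rate at ``cfg.t_cur`` under the configured schedule."""
    return cfg.at(cfg.t_cur)


def schedule_curve(cfg: ScheduleConfig) -> np.ndarray:
    """The full schedule as an array over epochs 0..total_epochs inclusive."""
    return np.array([cfg.at(e) for e in range(cfg.total_epochs + 1)])
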