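"""Synthetic insect-trap scenes and a stochastic detector simulator.

The generator emulates the statistical structure of large multi-class trap
image collections: about 7.6 labeled boxes per image (overdispersed across
images), 24 classes with a near-500x imbalance between the most and least
abundant, objects occupying mostly under 0.4% of the image area, adhesion
clusters of mutually overlapping same-class boxes, and a fraction of real
objects that carry no annotation.  The detector simulator perturbs the full
object list (labeled or not) with misses, corner jitter, duplicate boxes
and background false positives — so detections of unlabeled objects score
as false positives against the visible annotations, reproducing the
FP-inflation effect of missing labels.

All generation is a pure function of (config, seed).

Missing labels and the 7.6 calibration: the published figure is the mean of
*labeled* boxes per image, so the generator draws the full object count
from a negative binomial with mean ``boxes_per_image / (1 - p_missing_label)``
and drops each label independently with probability ``p_missing_label``;
the labeled count then has mean ``boxes_per_image`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import Annotation, Box, Detection, ImageSize
from .pest24 import pest24_class_weights

__all__ = [
    "SceneConfig",
    "DetectorNoiseConfig",
    "SceneTruth",
    "SceneStats",
    "generate_scenes",
    "simulate_detector",
    "simulate_detections",
    "render_scene",
    "scene_stats",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic trap-image world.

    ``boxes_per_image`` is the mean number of *labeled* boxes per image
    (negative binomial across images, dispersion ``count_dispersion``).
    Relative box area is log-normal; the default location/scale put ~95% of
    draws below 0.4% of the image.  ``adhesion`` controls clusters of
    overlapping same-class boxes: each new object starts a cluster with
    probability ``adhesion_cluster_prob``, whose extra members are placed by
    rejection sampling until their IoU with the cluster seed falls in
    ``adhesion_iou_range``.
    """

    image_size: ImageSize = ImageSize(2095, 1944)
    num_classes: int = 24
    class_weights: tuple[float, ...] | None = None  # None -> benchmark instance proportions
    boxes_per_image: float = 7.6
    count_dispersion: float = 8.0
    scale_log_mean: float = math.log(0.0013)
    scale_log_sd: float = 0.7
    aspect_log_sd: float = 0.25
    adhesion_cluster_prob: float = 0.25
    adhesion_cluster_size: tuple[int, int] = (2, 4)
    adhesion_iou_range: tuple[float, float] = (0.15, 0.6)
    adhesion_max_retries: int = 1000
    p_missing_label: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_missing_label < 1.0):
            raise ValueError(f"p_missing_label must be in [0,1), got {self.p_missing_label}")
        if self.boxes_per_image <= 0 or self.count_dispersion <= 0:
            raise ValueError("boxes_per_image and count_dispersion must be positive")
        lo, hi = self.adhesion_iou_range
        if not (0.0 <= lo < hi < 1.0):
            raise ValueError(f"adhesion_iou_range must satisfy 0 <= lo < hi < 1, got {self.adhesion_iou_range}")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights)
            if len(w) != self.num_classes or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("class_weights must have num_classes entries summing to 1")

    def resolved_class_weights(self) -> np.ndarray:
        if self.class_weights is not None:
            return np.asarray(self.class_weights, dtype=float)
        if self.num_classes == 24:
            return pest24_class_weights()
        return np.full(self.num_classes, 1.0 / self.num_classes)


@dataclass(frozen=True)
class DetectorNoiseConfig:
    """Output statistics of a simulated (trained) detector.

    ``p_detect`` may be a scalar or a per-class tuple.  Confidence
    parameters are either a float (a constant score) or a Beta(a, b) pair.
    """

    p_detect: float | tuple[float, ...] = 0.9
    corner_jitter: float = 0.05  # sd as a fraction of the box side
    duplicates_mean: float = 0.3  # Poisson mean of extra boxes per detected object
    fp_rate: float = 1.0  # Poisson mean of background false positives per image
    conf_tp: float | tuple[float, float] = (5.0, 2.0)
    conf_fp: float | tuple[float, float] = (2.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        ps = self.p_detect if isinstance(self.p_detect, tuple) else (self.p_detect,)
        if any(not (0.0 <= p <= 1.0) for p in ps):
            raise ValueError("p_detect probabilities must lie in [0,1]")
        if self.corner_jitter < 0 or self.duplicates_mean < 0 or self.fp_rate < 0:
            raise ValueError("noise rates must be non-negative")

    @classmethod
    def perfect(cls) -> "DetectorNoiseConfig":
        """A detector that reproduces the full truth exactly, with confidence 1."""
        return cls(p_detect=1.0, corner_jitter=0.0, duplicates_mean=0.0, fp_rate=0.0,
                   conf_tp=1.0, conf_fp=1.0)


@dataclass(frozen=True)
class SceneTruth:
    """One scene: the full object list and which objects carry a label."""

    image_id: str
    image_size: ImageSize
    objects: tuple[Annotation, ...]
    labeled: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.objects) != len(self.labeled):
            raise ValueError("labeled mask must align with objects")

    @property
    def visible(self) -> list[Annotation]:
        """The labeled subset — what an annotator actually recorded."""
        return [o for o, lab in zip(self.objects, self.labeled) if lab]

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def n_labeled(self) -> int:
        return sum(self.labeled)


class AdhesionError(RuntimeError):
    pass


def _sample_box(cfg: SceneConfig, rng: np.random.Generator) -> Box:
    """One box with log-normal relative area and mild log-normal aspect."""
    W, H = cfg.image_size.width, cfg.image_size.height
    rel = float(rng.lognormal(cfg.scale_log_mean, cfg.scale_log_sd))
    area = min(rel, 0.25) * W * H
    aspect = float(rng.lognormal(0.0, cfg.aspect_log_sd))
    w = min(max(math.sqrt(area * aspect), 2.0), W - 1.0)
    h = min(max(math.sqrt(area / aspect), 2.0), H - 1.0)
    cx = rng.uniform(w / 2.0, W - w / 2.0)
    cy = rng.uniform(h / 2.0, H - h / 2.0)
    return Box(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


def _iou_boxes(a: Box, b: Box) -> float:
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _adhesion_member(seed_box: Box, cfg: SceneConfig, rng: np.random.Generator) -> Box:
    """Rejection-sample a neighbour whose IoU with the seed lies in range."""
    W, H = cfg.image_size.width, cfg.image_size.height
    lo, hi = cfg.adhesion_iou_range
    w0, h0 = seed_box.width, seed_box.height
    for _ in range(cfg.adhesion_max_retries):
        s = float(rng.lognormal(0.0, 0.15))
        w, h = min(w0 * s, W - 1.0), min(h0 * s, H - 1.0)
        cx0, cy0 = seed_box.center
        cx = cx0 + rng.uniform(-w0, w0)
        cy = cy0 + rng.uniform(-h0, h0)
        cx = min(max(cx, w / 2.0), W - w / 2.0)
        cy = min(max(cy, h / 2.0), H - h / 2.0)
        cand = Box(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)
        if lo <= _iou_boxes(seed_box, cand) <= hi:
            return cand
    raise AdhesionError(
        f"could not place an adhesion neighbour with IoU in {cfg.adhesion_iou_range} "
        f"after {cfg.adhesion_max_retries} retries (seed box {seed_box.as_tuple()})"
    )


def generate_scenes(cfg: SceneConfig | None = None, n: int = 1, seed: int | None = None) -> list[SceneTruth]:
    """Generate n scenes; reproducible given (config, seed).

    ``seed`` overrides ``cfg.seed`` when given.
    """
    cfg = cfg or SceneConfig()
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    weights = cfg.resolved_class_weights()
    mean_full = cfg.boxes_per_image / (1.0 - cfg.p_missing_label)
    r = cfg.count_dispersion
    p_nb = r / (r + mean_full)
    lo_k, hi_k = cfg.adhesion_cluster_size
    scenes: list[SceneTruth] = []
    for i in range(n):
        image_id = f"scene_{i:05d}"
        n_full = int(rng.negative_binomial(r, p_nb))
        objects: list[Annotation] = []
        while len(objects) < n_full:
            remaining = n_full - len(objects)
            class_id = int(rng.choice(cfg.num_classes, p=weights))
            seed_box = _sample_box(cfg, rng)
            objects.append(Annotation(image_id=image_id, class_id=class_id, box=seed_box))
            if remaining >= 2 and rng.random() < cfg.adhesion_cluster_prob:
                k = int(min(rng.integers(lo_k, hi_k + 1), remaining))
                for _ in range(k - 1):
                    member = _adhesion_member(seed_box, cfg, rng)
                    objects.append(Annotation(image_id=image_id, class_id=class_id, box=member))
        labeled = tuple(bool(v) for v in (rng.random(n_full) >= cfg.p_missing_label))
        scenes.append(
            SceneTruth(
                image_id=image_id,
                image_size=cfg.image_size,
                objects=tuple(objects),
                labeled=labeled,
            )
        )
    return scenes


def _sample_conf(param: float | tuple[float, float], rng: np.random.Generator) -> float:
    if isinstance(param, tuple):
        return float(rng.beta(*param))
    return float(param)


def _jitter_box(b: Box, sd_frac: float, size: ImageSize, rng: np.random.Generator) -> Box:
    if sd_frac == 0.0:
        return b
    w, h = b.width, b.height
    x1 = b.x1 + rng.normal(0.0, sd_frac * w)
    x2 = b.x2 + rng.normal(0.0, sd_frac * w)
    y1 = b.y1 + rng.normal(0.0, sd_frac * h)
    y2 = b.y2 + rng.normal(0.0, sd_frac * h)
    x1, x2 = min(x1, x2), max(x1, x2)
    y1, y2 = min(y1, y2), max(y1, y2)
    x1 = min(max(x1, 0.0), size.width - 1.0)
    y1 = min(max(y1, 0.0), size.height - 1.0)
    x2 = min(max(x2, x1 + 1.0), float(size.width))
    y2 = min(max(y2, y1 + 1.0), float(size.height))
    return Box(x1, y1, x2, y2)


def simulate_detector(
    truth: SceneTruth,
    noise: DetectorNoiseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[Detection]:
    """Simulate a detector's output on one scene.

    Every object in the *full* list — labeled or not — is independently
    detected with ``p_detect``; detected boxes are corner-jittered and may
    spawn duplicate boxes; background false positives are placed uniformly.
    Pass an explicit ``rng`` to stream several scenes from one seed
    (:func:`simulate_detections` does this).
    """
    noise = noise or DetectorNoiseConfig()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    out: list[Detection] = []
    for obj in truth.objects:
        p = (
            noise.p_detect[obj.class_id]
            if isinstance(noise.p_detect, tuple)
            else noise.p_detect
        )
        if rng.random() >= p:
            continue
        box = _jitter_box(obj.box, noise.corner_jitter, truth.image_size, rng)
        out.append(
            Detection(
                image_id=truth.image_id,
                class_id=obj.class_id,
                box=box,
                confidence=_sample_conf(noise.conf_tp, rng),
            )
        )
        for _ in range(int(rng.poisson(noise.duplicates_mean))):
            dup = _jitter_box(obj.box, max(noise.corner_jitter, 0.02), truth.image_size, rng)
            out.append(
                Detection(
                    image_id=truth.image_id,
                    class_id=obj.class_id,
                    box=dup,
                    confidence=_sample_conf(noise.conf_tp, rng),
                )
            )
    W, H = truth.image_size.width, truth.image_size.height
    for _ in range(int(rng.poisson(noise.fp_rate))):
        w = rng.uniform(10.0, max(20.0, 0.05 * W))
        h = rng.uniform(10.0, max(20.0, 0.05 * H))
        cx = rng.uniform(w / 2.0, W - w / 2.0)
        cy = rng.uniform(h / 2.0, H - h / 2.0)
        out.append(
            Detection(
                image_id=truth.image_id,
                class_id=int(rng.integers(0, max(1, _max_class(truth) + 1))),
                box=Box(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0),
                confidence=_sample_conf(noise.conf_fp, rng),
            )
        )
    return out


def _max_class(truth: SceneTruth) -> int:
    return max((o.class_id for o in truth.objects), default=23)


def simulate_detections(
    truths: Sequence[SceneTruth], noise: DetectorNoiseConfig | None = None
) -> list[Detection]:
    """Simulate the detector over many scenes with one seeded stream."""
    noise = noise or DetectorNoiseConfig()
    rng = np.random.default_rng(noise.seed)
    out: list[Detection] = []
    for truth in truths:
        out.extend(simulate_detector(truth, noise, rng))
    return out


def render_scene(
    truth: SceneTruth, cfg: SceneConfig | None = None, seed: int = 0
) -> np.ndarray:
    """Rasterize a scene as a grayscale uint8 image: a noisy background with
    one filled ellipse inscribed in each object's box.  Deterministic given
    the seed; sufficient for exercising augmentation geometry, not a
    photorealistic render."""
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(seed)
    H, W = truth.image_size.height, truth.image_size.width
    img = rng.normal(60.0, 8.0, size=(H, W))
    for obj in truth.objects:
        b = obj.box
        x1, y1 = int(math.floor(b.x1)), int(math.floor(b.y1))
        x2, y2 = int(math.ceil(b.x2)), int(math.ceil(b.y2))
        x1, y1 = max(x1, 0), max(y1, 0)
        x2, y2 = min(x2, W), min(y2, H)
        if x2 <= x1 or y2 <= y1:
            continue
        yy, xx = np.mgrid[y1:y2, x1:x2]
        cx, cy = b.center
        a = max(b.width / 2.0, 0.5)
        c = max(b.height / 2.0, 0.5)
        inside = ((xx + 0.5 - cx) / a) ** 2 + ((yy + 0.5 - cy) / c) ** 2 <= 1.0
        img[y1:y2, x1:x2][inside] = 170.0 + 15.0 * rng.random()
    return np.clip(img, 0, 255).astype(np.uint8)


@dataclass
class SceneStats:
    """Summary statistics over a batch of scenes, for calibration checks."""

    n_scenes: int
    labeled_per_image: np.ndarray
    objects_per_image: np.ndarray
    relative_scales: np.ndarray  # of labeled boxes
    class_counts: np.ndarray  # of labeled boxes
    mean_labeled_per_image: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_labeled_per_image = (
            float(self.labeled_per_image.mean()) if self.n_scenes else 0.0
        )

    def frac_scale_below(self, threshold: float) -> float:
        if len(self.relative_scales) == 0:
            return 0.0
        return float((self.relative_scales < threshold).mean())


def scene_stats(truths: Sequence[SceneTruth], num_classes: int | None = None) -> SceneStats:
    """Aggregate labeled-box counts, relative scales and class frequencies."""
    if not truths:
        raise ValueError("scene_stats needs at least one scene")
    labeled = np.array([t.n_labeled for t in truths], dtype=int)
    totals = np.array([t.n_objects for t in truths], dtype=int)
    scales: list[float] = []
    classes: list[int] = []
    for t in truths:
        area = t.image_size.area
        for a in t.visible:
            scales.append(a.box.area / area)
            classes.append(a.class_id)
    if num_classes is None:
        num_classes = max(classes, default=-1) + 1
    counts = np.bincount(np.array(classes, dtype=int), minlength=num_classes) if classes else np.zeros(num_classes, dtype=int)
    return SceneStats(
        n_scenes=len(truths),
        labeled_per_image=labeled,
        objects_per_image=totals,
        relative_scales=np.array(scales),
        class_counts=counts,
    )
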