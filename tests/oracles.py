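"""Independent reference implementations used as test oracles.

Everything here is written with plain scalar loops and its own arithmetic,
deliberately sharing no code with the package, so agreement between the two
is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np

from pestbox.geometry import Box, Detection


def iou_ref(a: Box, b: Box) -> float:
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    ua = (a.x2 - a.x1) * (a.y2 - a.y1) + (b.x2 - b.x1) * (b.y2 - b.y1) - inter
    return inter / ua


def proximity_ref(a: Box, b: Box) -> float:
    """Joint min-max normalization per axis, then corner-wise L1 sums."""
    xs = [a.x1, a.x2, b.x1, b.x2]
    ys = [a.y1, a.y2, b.y1, b.y2]
    sx = max(xs) - min(xs)
    sy = max(ys) - min(ys)

    def nx(v):
        return (v - min(xs)) / sx if sx > 0 else 0.0

    def ny(v):
        return (v - min(ys)) / sy if sy > 0 else 0.0

    return (
        abs(nx(a.x1) - nx(b.x1))
        + abs(ny(a.y1) - ny(b.y1))
        + abs(nx(a.x2) - nx(b.x2))
        + abs(ny(a.y2) - ny(b.y2))
    )


def confluence_ref(
    dets: list[Detection],
    proximity_threshold: float = 2.0,
    confidence_floor: float = 0.05,
    removal_threshold: float | None = None,
    class_aware: bool = True,
) -> list[Detection]:
    """Step-by-step transcription of the two-stage confluence procedure."""
    rem = proximity_threshold if removal_threshold is None else removal_threshold
    cand = [i for i, d in enumerate(dets) if d.confidence >= confidence_floor]
    kept: list[int] = []
    groups = sorted({dets[i].class_id for i in cand}) if class_aware else [None]
    for c in groups:
        pool = [i for i in cand if c is None or dets[i].class_id == c]
        while pool:
            pairP = {}
            for a in pool:
                for b in pool:
                    if a < b:
                        pairP[(a, b)] = proximity_ref(dets[a].box, dets[b].box)

            def getP(a, b):
                return pairP[(min(a, b), max(a, b))]

            partners = {
                i: [j for j in pool if j != i and getP(i, j) < proximity_threshold]
                for i in pool
            }
            lonely = [i for i in pool if not partners[i]]
            kept.extend(lonely)
            pool = [i for i in pool if partners[i]]
            if not pool:
                break
            best = min(
                pool,
                key=lambda i: (
                    min(getP(i, j) for j in partners[i]) / dets[i].confidence,
                    -dets[i].confidence,
                    i,
                ),
            )
            kept.append(best)
            pool = [j for j in pool if j != best and getP(best, j) >= rem]
    return [dets[i] for i in sorted(kept)]


def nms_ref(
    dets: list[Detection],
    iou_threshold: float = 0.5,
    class_aware: bool = True,
    diou: bool = False,
) -> list[Detection]:
    """Brute-force greedy NMS / DIoU-NMS."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    kept: list[int] = []
    for i in order:
        drop = False
        for j in kept:
            if class_aware and dets[i].class_id != dets[j].class_id:
                continue
            a, b = dets[j].box, dets[i].box
            score = iou_ref(a, b)
            if diou:
                d2 = ((a.x1 + a.x2) / 2 - (b.x1 + b.x2) / 2) ** 2 + (
                    (a.y1 + a.y2) / 2 - (b.y1 + b.y2) / 2
                ) ** 2
                cw = max(a.x2, b.x2) - min(a.x1, b.x1)
                ch = max(a.y2, b.y2) - min(a.y1, b.y1)
                score -= d2 / (cw**2 + ch**2)
            if score > iou_threshold:
                drop = True
                break
        if not drop:
            kept.append(i)
    return [dets[i] for i in sorted(kept)]


def average_precision_ref(dets, annots, iou_threshold: float = 0.5) -> float:
    """Brute-force all-point AP: rank, greedily match per image, build the
    precision envelope by explicit maxima, and sum rectangles."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    matched = [False] * len(annots)
    flags = []
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, a in enumerate(annots):
            if matched[j] or a.image_id != dets[i].image_id:
                continue
            v = iou_ref(dets[i].box, a.box)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    tp = fp = 0
    recalls, precisions = [], []
    for f in flags:
        tp += int(f)
        fp += int(not f)
        recalls.append(tp / len(annots))
        precisions.append(tp / (tp + fp))
    ap = 0.0
    prev_r = 0.0
    for k, r in enumerate(recalls):
        if r > prev_r:
            p_env = max(precisions[k:])
            ap += (r - prev_r) * p_env
            prev_r = r
    return ap


def make_random_detections(
    rng: np.random.Generator,
    n_max: int = 6,
    n_classes: int = 2,
    image_id: str = "img0",
    clustered: bool = True,
) -> list[Detection]:
    """Random overlapping detection sets on a 100x100 image."""
    n = int(rng.integers(1, n_max + 1))
    centers = rng.uniform(15, 85, size=(2, 2)) if clustered else None
    dets = []
    for _ in range(n):
        if clustered and rng.random() < 0.8:
            cx, cy = centers[int(rng.integers(2))] + rng.normal(0, 6, 2)
        else:
            cx, cy = rng.uniform(10, 90, 2)
        w, h = rng.uniform(5, 25, 2)
        x1 = float(np.clip(cx - w / 2, 0, 98))
        y1 = float(np.clip(cy - h / 2, 0, 98))
        x2 = float(np.clip(x1 + w, x1 + 1, 100))
        y2 = float(np.clip(y1 + h, y1 + 1, 100))
        dets.append(
            Detection(
                image_id=image_id,
                class_id=int(rng.integers(n_classes)),
                box=Box(x1, y1, x2, y2),
                confidence=round(float(rng.uniform(0.02, 1.0)), 6),
            )
        )
    return dets
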