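"""Desk-scale end-to-end experiment: generate scenes, simulate a detector,
suppress with each configured method, and evaluate detection + counting
metrics side by side.

The run is a pure function of the configuration and seed: re-running with
the manifest's config snapshot reproduces byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .dataset_io import write_detections_csv
from .evaluation import counting_metrics, counting_pairs, evaluate_detections, summarize
from .geometry import ImageSize
from .suppression import SuppressionConfig, suppress
from .synthetic import DetectorNoiseConfig, SceneConfig, generate_scenes, simulate_detections

__all__ = ["ExperimentConfig", "RunManifest", "run_experiment", "adhesion_benchmark_config"]

METHODS = ("confluence", "nms", "diou-nms")


def adhesion_benchmark_config(seed: int = 42) -> tuple[SceneConfig, DetectorNoiseConfig, SuppressionConfig]:
    """The packaged adhesion benchmark: dense same-class clusters with many
    jittered duplicate detections whose confidences carry no localization
    signal.

    This is the regime where coherence-based selection pays off: confidence-led
    greedy suppression keeps whichever duplicate scored highest and suppresses
    its overlapping neighbours, while confluence retains the box most
    consistent with its cluster (minimal weighted proximity).  The benchmark
    runs confluence with ``removal_threshold = 0.5`` — clusters still form at
    P < 2, but only near-coincident boxes are deleted around a retained box;
    with the removal threshold left at 2, every overlapping neighbour of a
    retained box is necessarily deleted (any overlapping same-size pair has
    P < 2), which makes dense-scene retention impossible by construction.
    """
    scene = SceneConfig(
        adhesion_cluster_prob=0.6,
        adhesion_iou_range=(0.55, 0.75),
        boxes_per_image=6.0,
        p_missing_label=0.0,
        seed=seed,
    )
    noise = DetectorNoiseConfig(
        p_detect=1.0,
        corner_jitter=0.06,
        duplicates_mean=3.0,
        fp_rate=0.5,
        conf_tp=(2.0, 2.0),
        seed=seed + 1,
    )
    suppression = SuppressionConfig(removal_threshold=0.5)
    return scene, noise, suppression


@dataclass(frozen=True)
class ExperimentConfig:
    """Top-level configuration; every field overridable from the YAML config."""

    n_images: int = 50
    seed: int = 0
    methods: tuple[str, ...] = METHODS
    scene: SceneConfig = field(default_factory=SceneConfig)
    detector: DetectorNoiseConfig = field(default_factory=DetectorNoiseConfig)
    suppression: SuppressionConfig = field(default_factory=SuppressionConfig)
    eval_iou: float = 0.5
    eval_conf: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown suppression methods {sorted(unknown)}")
        if not self.methods:
            raise ValueError("configure at least one suppression method")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ExperimentConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        if "scene" in data:
            scene = dict(data.pop("scene"))
            if "image_size" in scene:
                scene["image_size"] = ImageSize(*scene["image_size"])
            for key in ("adhesion_cluster_size", "adhesion_iou_range", "class_weights"):
                if key in scene and scene[key] is not None:
                    scene[key] = tuple(scene[key])
            kwargs["scene"] = SceneConfig(**scene)
        if "detector" in data:
            det = dict(data.pop("detector"))
            for key in ("p_detect", "conf_tp", "conf_fp"):
                if key in det and isinstance(det[key], list):
                    det[key] = tuple(det[key])
            kwargs["detector"] = DetectorNoiseConfig(**det)
        if "suppression" in data:
            kwargs["suppression"] = SuppressionConfig(**data.pop("suppression"))
        if "methods" in data:
            kwargs["methods"] = tuple(data.pop("methods"))
        kwargs.update(data)
        return cls(**kwargs)


@dataclass
class RunManifest:
    """Record of one experiment run: config snapshot, seeds, versions, the
    artifacts written and per-stage wall time (informational only)."""

    config: dict[str, Any]
    seeds: dict[str, int]
    versions: dict[str, str]
    outputs: dict[str, str]
    wall_time_s: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _config_snapshot(cfg: ExperimentConfig) -> dict[str, Any]:
    def unpack(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: unpack(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [unpack(v) for v in obj]
        return obj

    return unpack(cfg)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> RunManifest:
    """Run the full generate → simulate → suppress → evaluate pipeline.

    Writes the raw simulated detections, per-method retained detections and
    metric reports, a side-by-side comparison table (mAP, mPrecision,
    mRecall, mF1, counting RMSE/R^2) and a manifest, all under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    times: dict[str, float] = {}

    t0 = time.perf_counter()
    scene_cfg = dataclasses.replace(cfg.scene, seed=cfg.seed)
    det_cfg = dataclasses.replace(cfg.detector, seed=cfg.seed + 1)
    truths = generate_scenes(scene_cfg, cfg.n_images)
    annots = [a for t in truths for a in t.visible]
    truth_counts = {t.image_id: t.n_objects for t in truths}
    times["generate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    raw_dets = simulate_detections(truths, det_cfg)
    raw_path = out_dir / "detections_raw.csv"
    write_detections_csv(raw_path, raw_dets)
    outputs["detections_raw"] = str(raw_path)
    times["simulate"] = time.perf_counter() - t0

    rows = []
    for method in cfg.methods:
        t0 = time.perf_counter()
        kept = suppress(raw_dets, method, cfg.suppression)
        kept_path = out_dir / f"kept_{method}.csv"
        write_detections_csv(kept_path, kept)
        outputs[f"kept_{method}"] = str(kept_path)

        per_class = evaluate_detections(
            kept, annots, cfg.scene.num_classes, cfg.eval_iou, cfg.eval_conf
        )
        macro = summarize(per_class)
        counting = counting_metrics(counting_pairs(kept, truth_counts, cfg.eval_conf))
        report = {
            "method": method,
            "macro": macro,
            "per_class": [dataclasses.asdict(m) for m in per_class],
            "counting": {
                "rmse": counting.rmse,
                "r2": counting.r2,
                "slope": counting.slope,
                "intercept": counting.intercept,
                "n_images": counting.n_images,
            },
        }
        report_path = out_dir / f"report_{method}.json"
        with open(report_path, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs[f"report_{method}"] = str(report_path)
        times[f"{method}"] = time.perf_counter() - t0
        rows.append(
            {
                "method": method,
                "n_kept": len(kept),
                **{k: macro[k] for k in ("mAP", "mPrecision", "mRecall", "mF1")},
                "counting_rmse": counting.rmse,
                "counting_r2": counting.r2,
            }
        )

    table = pd.DataFrame(rows)
    table_path = out_dir / "comparison.csv"
    table.to_csv(table_path, index=False)
    outputs["comparison"] = str(table_path)

    manifest = RunManifest(
        config=_config_snapshot(cfg),
        seeds={"base": cfg.seed, "scene": scene_cfg.seed, "detector": det_cfg.seed},
        versions={"pestbox": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        outputs=outputs,
        wall_time_s={k: round(v, 4) for k, v in times.items()},
    )
    manifest.to_json(out_dir / "manifest.json")
    outputs["manifest"] = str(out_dir / "manifest.json")
    return manifest


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and obj != obj:  # NaN -> null
        return None
    return obj
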