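"""Run configuration: thresholds, geometry and seeds in one YAML document.

The config is a flat mapping with a handful of sections (``rig``,
``nozzles``, ``plots``, ``thresholds``, ``error_model``, ``scenario``).
Unknown keys are errors (fail-fast), every threshold is range-checked, and
a config round-trips through YAML losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .scene import CameraRig, Plot
from .sprayer import NozzleArray
from .synthetic import ErrorModel, ScenarioConfig, default_plots

__all__ = ["Thresholds", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class Thresholds:
    """Every tunable decision threshold in the evaluation pipeline."""

    confidence: float = 0.001     # raw-detection confidence filter
    nms_iou: float = 0.5          # class-wise NMS suppression threshold
    match_iou: float = 0.5        # image-level matching threshold
    coverage: float = 0.25        # plant-level detection-covers-plant ratio
    link_radius_m: float = 0.09   # ground-truth plant linking radius
    cluster_radius_m: float = 0.09  # background-FP dedup radius
    near_radius_m: float = 0.10   # "close to a sprayed potato" distance
    hit_margin_m: float = 0.0     # plant-box dilation for field scoring
    speed_mps: float = 0.0        # travel speed (0 = instantaneous switching)

    def __post_init__(self) -> None:
        for name in ("confidence", "nms_iou", "match_iou", "coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name}={v} outside [0, 1]")
        for name in ("link_radius_m", "cluster_radius_m", "near_radius_m",
                     "hit_margin_m", "speed_mps"):
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    rig: CameraRig = field(default_factory=CameraRig)
    nozzles: NozzleArray = field(default_factory=NozzleArray)
    plots: tuple[Plot, ...] = field(default_factory=lambda: tuple(default_plots()))
    thresholds: Thresholds = field(default_factory=Thresholds)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0
    dedupe_background: bool = True

    def scenario(self) -> ScenarioConfig:
        return ScenarioConfig(
            plots=self.plots, rig=self.rig, nozzles=self.nozzles, seed=self.seed
        )

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "dedupe_background": self.dedupe_background,
            "rig": dataclasses.asdict(self.rig),
            "nozzles": dataclasses.asdict(self.nozzles),
            "plots": [dataclasses.asdict(p) for p in self.plots],
            "thresholds": dataclasses.asdict(self.thresholds),
            "error_model": dataclasses.asdict(self.error_model),
        }


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    # YAML has no tuple type; coerce list-valued fields back
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def config_from_dict(data: dict) -> RunConfig:
    known = {"seed", "dedupe_background", "rig", "nozzles", "plots",
             "thresholds", "error_model"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "dedupe_background" in data:
        kwargs["dedupe_background"] = bool(data["dedupe_background"])
    if "rig" in data:
        kwargs["rig"] = _build(CameraRig, data["rig"], "rig")
    if "nozzles" in data:
        kwargs["nozzles"] = _build(NozzleArray, data["nozzles"], "nozzles")
    if "plots" in data:
        kwargs["plots"] = tuple(
            _build(Plot, p, f"plots[{i}]") for i, p in enumerate(data["plots"])
        )
    if "thresholds" in data:
        kwargs["thresholds"] = _build(Thresholds, data["thresholds"], "thresholds")
    if "error_model" in data:
        kwargs["error_model"] = _build(ErrorModel, data["error_model"],
                                       "error_model")
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.as_dict(), sort_keys=True), encoding="utf-8"
    )
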