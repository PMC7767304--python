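"""Synthetic field scenes and detector outputs with realistic error structure.

The generator emulates the structure of an eight-plot sugar-beet field
trial: 2 m x 12.5 m plots (four on sandy, four on peaty soil, half with a
barley cover crop), sugar beets on a row lattice (0.5 m inter-row, 0.19 m
intra-row), volunteer potatoes planted at random locations, imaged by a
four-camera rig triggered every 0.25 m so that each plant is seen up to
three times.  Per-frame ground-truth boxes are derived by clipping each
plant's world box to the frame footprint, so partially visible edge plants
appear exactly as they do to an annotator.

Detector errors are phenomenological, not rendered: position-dependent
misses (strongly elevated near the upper image edge, where over-illumination
hides plants), box jitter, merges of adjacent potatoes into one box, splits
of one potato into several boxes, sugar beets misclassified as potato, and
background false positives from a spatial Poisson process whose intensity
doubles on peaty soil (more small unknown weeds).  All randomness flows from
explicit integer seeds; one stream per plot, so plots are independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image_eval import GroundTruthBox
from .postprocess import DetectionEvent
from .scene import (
    BoundingBox,
    CameraRig,
    Frame,
    IMAGE,
    Plant,
    Plot,
    POTATO,
    SUGAR_BEET,
    WORLD,
    frame_footprint,
    world_to_image,
)
from .sprayer import NozzleArray

__all__ = [
    "ErrorModel",
    "ScenarioConfig",
    "PlotScene",
    "Scene",
    "default_plots",
    "generate_scene",
    "generate_detections",
    "PERFECT_DETECTOR",
]


@dataclass(frozen=True)
class ErrorModel:
    """Per-observation detector error rates and noise magnitudes.

    The defaults are a calibration preset chosen so that the pooled
    image-level precision/recall of the potato class lands near 0.84/0.57
    on the default scenario; they are not measurements of any real detector.
    """

    miss_prob_base: float = 0.235
    #: Miss probability for observations whose box centre lies in the top
    #: image band (over-illuminated strip under the camera cover).
    miss_prob_top_edge: float = 0.92
    #: Fraction of the image height counted as "near the upper edge".
    top_edge_fraction: float = 0.30
    #: Probability that a pair of nearby same-frame potato boxes is fused.
    merge_prob: float = 0.03
    #: World distance below which two potato detections are merge candidates.
    merge_distance_m: float = 0.30
    #: Probability that a detected potato observation splits into two boxes.
    split_prob: float = 0.03
    #: Probability that a detected beet observation is emitted as potato.
    beet_as_potato_prob: float = 0.004
    #: Background false-positive objects per square metre (sandy soil).
    background_fp_rate_per_m2: float = 0.15
    #: Intensity multiplier on peaty soil.
    peaty_rate_multiplier: float = 2.0
    #: Per-observation miss probability for background objects.
    background_miss_prob: float = 0.70
    #: Std of the Gaussian centre jitter added to detection boxes, metres.
    box_jitter_sigma_m: float = 0.006
    plant_confidence_range: tuple[float, float] = (0.30, 1.00)
    background_confidence_range: tuple[float, float] = (0.02, 0.55)
    misclass_confidence_range: tuple[float, float] = (0.02, 0.60)

    def __post_init__(self) -> None:
        for name in ("miss_prob_base", "miss_prob_top_edge", "top_edge_fraction",
                     "merge_prob", "split_prob", "beet_as_potato_prob",
                     "background_miss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.background_fp_rate_per_m2 < 0 or self.peaty_rate_multiplier < 0:
            raise ValueError("rates must be non-negative")


#: Error-free detector: every observation detected perfectly.
PERFECT_DETECTOR = ErrorModel(
    miss_prob_base=0.0, miss_prob_top_edge=0.0, merge_prob=0.0, split_prob=0.0,
    beet_as_potato_prob=0.0, background_fp_rate_per_m2=0.0,
    box_jitter_sigma_m=0.0, plant_confidence_range=(0.9, 1.0),
)


def default_plots() -> list[Plot]:
    """The eight trial plots: 1-4 sandy, 5-8 peaty; barley on 1, 4, 5, 8."""
    soil = ["sandy"] * 4 + ["peaty"] * 4
    barley = [True, False, False, True, True, False, False, True]
    return [
        Plot(plot_id=i + 1, soil_type=soil[i], contains_barley=barley[i])
        for i in range(8)
    ]


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a synthetic trial; the seed determines everything."""

    plots: tuple[Plot, ...] = ()
    rig: CameraRig = field(default_factory=CameraRig)
    nozzles: NozzleArray = field(default_factory=NozzleArray)
    seed: int = 0
    #: Min/max volunteer potatoes planted per plot (uniform draw).
    potatoes_per_plot: tuple[int, int] = (30, 38)
    #: Across-track world offset of the plot's left edge (plot centred
    #: under the 2.8 m boom).
    plot_across_offset_m: float = 0.4
    #: Along-track gap between consecutive plots' world extents.
    plot_gap_m: float = 5.0
    beet_size_range_m: tuple[float, float] = (0.09, 0.15)
    potato_size_range_m: tuple[float, float] = (0.10, 0.15)
    #: Uniform +/- jitter of beet positions around the sowing lattice.
    row_jitter_m: float = 0.01
    #: Minimum separation between potato centres (they are physical plants).
    min_potato_separation_m: float = 0.30
    #: Minimum distance from a potato centre to any sown beet centre; a
    #: tuber dropped onto a sown beet would not leave both plants intact.
    min_potato_to_beet_m: float = 0.18
    #: A plant view is annotated when at least this fraction of its world
    #: box area falls inside the frame footprint.
    min_visible_fraction: float = 0.5
    #: Optional Gaussian trigger-position noise (0 = exact 0.25 m spacing).
    trigger_jitter_sigma_m: float = 0.0

    def __post_init__(self) -> None:
        if not self.plots:
            object.__setattr__(self, "plots", tuple(default_plots()))


@dataclass
class PlotScene:
    """One plot's world: frames, true plants, per-frame ground truth."""

    plot: Plot
    along_offset_m: float
    frames: dict[str, Frame]
    plants: list[Plant]
    gts_by_frame: dict[str, list[GroundTruthBox]]
    background_boxes: list[BoundingBox] = field(default_factory=list)

    @property
    def frame_ids(self) -> list[str]:
        return sorted(self.frames)


@dataclass
class Scene:
    """A full multi-plot trial scene."""

    config: ScenarioConfig
    plot_scenes: list[PlotScene]

    @property
    def rig(self) -> CameraRig:
        return self.config.rig

    @property
    def frames(self) -> dict[str, Frame]:
        out: dict[str, Frame] = {}
        for ps in self.plot_scenes:
            out.update(ps.frames)
        return out

    @property
    def gts_by_frame(self) -> dict[str, list[GroundTruthBox]]:
        out: dict[str, list[GroundTruthBox]] = {}
        for ps in self.plot_scenes:
            out.update(ps.gts_by_frame)
        return out

    @property
    def plants(self) -> list[Plant]:
        return [p for ps in self.plot_scenes for p in ps.plants]

    @property
    def plot_of_frame(self) -> dict[str, int]:
        return {
            fid: ps.plot.plot_id for ps in self.plot_scenes for fid in ps.frames
        }

    @property
    def plot_of_plant(self) -> dict[str, int]:
        return {
            p.plant_id: ps.plot.plot_id
            for ps in self.plot_scenes
            for p in ps.plants
        }


def _plot_rng(seed: int, plot_id: int, stream: int) -> np.random.Generator:
    # one independent, reproducible stream per (plot, purpose)
    return np.random.default_rng([seed & 0x7FFFFFFF, plot_id, stream])


def _clip_to_footprint(
    wb: BoundingBox, frame: Frame, rig: CameraRig, min_fraction: float
) -> BoundingBox | None:
    fp = frame_footprint(frame, rig)
    w = min(wb.x_max, fp.x_max) - max(wb.x_min, fp.x_min)
    h = min(wb.y_max, fp.y_max) - max(wb.y_min, fp.y_min)
    if w <= 0 or h <= 0:
        return None
    if w * h / wb.area < min_fraction:
        return None
    return BoundingBox(max(wb.x_min, fp.x_min), max(wb.y_min, fp.y_min), w, h, WORLD)


def _generate_plot_scene(
    cfg: ScenarioConfig, plot: Plot, index: int
) -> PlotScene:
    rig = cfg.rig
    rng = _plot_rng(cfg.seed, plot.plot_id, 0)
    x0 = index * (plot.length_m + cfg.plot_gap_m)

    # frames: every trigger whose footprint touches the plot's along extent
    t_min = int(math.floor(-rig.fov_along_track / rig.trigger_spacing))
    t_max = int(math.ceil(plot.length_m / rig.trigger_spacing))
    frames: dict[str, Frame] = {}
    for cam in range(rig.n_cameras):
        ay = rig.camera_offsets_across_track[cam]
        for t in range(t_min, t_max + 1):
            jitter = (
                rng.normal(0.0, cfg.trigger_jitter_sigma_m)
                if cfg.trigger_jitter_sigma_m > 0 else 0.0
            )
            ax = x0 + t * rig.trigger_spacing + rig.fov_along_track + jitter
            fid = f"p{plot.plot_id}_c{cam}_t{t}"
            frames[fid] = Frame(fid, cam, t, (ax, ay))

    plants: list[Plant] = []

    def add_plant(cls: str, cx: float, cy: float, size: float) -> None:
        wb = BoundingBox(cx - size / 2, cy - size / 2, size, size, WORLD)
        pid = f"p{plot.plot_id}_{cls}_{len(plants):04d}"
        plants.append(Plant(pid, cls, wb))

    # sugar beets on the sowing lattice with small positional jitter
    n_per_row = int(math.floor(plot.length_m / plot.intra_row_m)) + 1
    for row_y in plot.row_positions(cfg.plot_across_offset_m):
        for i in range(n_per_row):
            cx = x0 + i * plot.intra_row_m
            cx += rng.uniform(-cfg.row_jitter_m, cfg.row_jitter_m)
            cy = row_y + rng.uniform(-cfg.row_jitter_m, cfg.row_jitter_m)
            size = rng.uniform(*cfg.beet_size_range_m)
            add_plant(SUGAR_BEET, cx, cy, size)

    # volunteer potatoes at random locations, kept physically separated
    n_pot = int(rng.integers(cfg.potatoes_per_plot[0], cfg.potatoes_per_plot[1] + 1))
    beet_pos = [p.world_box.center for p in plants]
    placed: list[tuple[float, float]] = []
    lo_y = cfg.plot_across_offset_m + 0.1
    hi_y = cfg.plot_across_offset_m + plot.width_m - 0.1
    attempts = 0
    while len(placed) < n_pot and attempts < 10000:
        attempts += 1
        cx = x0 + rng.uniform(0.1, plot.length_m - 0.1)
        cy = rng.uniform(lo_y, hi_y)
        if all(
            math.hypot(cx - px, cy - py) >= cfg.min_potato_separation_m
            for px, py in placed
        ) and all(
            math.hypot(cx - bx, cy - by) >= cfg.min_potato_to_beet_m
            for bx, by in beet_pos
        ):
            placed.append((cx, cy))
            add_plant(POTATO, cx, cy, rng.uniform(*cfg.potato_size_range_m))

    # per-frame ground truth by clipping world boxes to footprints
    gts_by_frame: dict[str, list[GroundTruthBox]] = {fid: [] for fid in frames}
    for plant in plants:
        for fid in sorted(frames):
            frame = frames[fid]
            clipped = _clip_to_footprint(
                plant.world_box, frame, rig, cfg.min_visible_fraction
            )
            if clipped is None:
                continue
            img_box = world_to_image(clipped, frame, rig)
            gt = GroundTruthBox(fid, plant.plant_class, img_box, plant.plant_id)
            gts_by_frame[fid].append(gt)
            plant.observations.append((fid, img_box))

    return PlotScene(
        plot=plot, along_offset_m=x0, frames=frames, plants=plants,
        gts_by_frame=gts_by_frame,
    )


def generate_scene(cfg: ScenarioConfig) -> Scene:
    """Generate plants, frames and per-frame annotations for every plot.

    Bit-reproducible: the same config (including seed) yields the same scene.
    """
    if cfg.plots and min(p.width_m for p in cfg.plots) < cfg.plots[0].inter_row_m:
        raise ValueError("plot narrower than one row spacing")
    plot_scenes = [
        _generate_plot_scene(cfg, plot, i) for i, plot in enumerate(cfg.plots)
    ]
    return Scene(config=cfg, plot_scenes=plot_scenes)


def _jittered_image_box(
    box: BoundingBox, rig: CameraRig, sigma_m: float, rng: np.random.Generator
) -> BoundingBox:
    if sigma_m <= 0:
        return box
    dx = rng.normal(0.0, sigma_m) / rig.scale_across
    dy = rng.normal(0.0, sigma_m) / rig.scale_along
    x = min(max(box.x_min + dx, 0.0), rig.image_width_px - 1.0)
    y = min(max(box.y_min + dy, 0.0), rig.image_height_px - 1.0)
    w = min(box.width, rig.image_width_px - x)
    h = min(box.height, rig.image_height_px - y)
    return BoundingBox(x, y, max(w, 1.0), max(h, 1.0), IMAGE)


def _miss_prob(box: BoundingBox, rig: CameraRig, model: ErrorModel) -> float:
    _, cy = box.center
    if cy < model.top_edge_fraction * rig.image_height_px:
        return model.miss_prob_top_edge
    return model.miss_prob_base


def _detections_for_plot(
    ps: PlotScene, rig: CameraRig, model: ErrorModel, rng: np.random.Generator,
) -> dict[str, list[DetectionEvent]]:
    dets: dict[str, list[DetectionEvent]] = {fid: [] for fid in ps.frames}

    def conf(rng_range: tuple[float, float]) -> float:
        return float(rng.uniform(*rng_range))

    # plant observations -> per-view detections with misses/splits/misclass
    for plant in ps.plants:
        for fid, img_box in plant.observations:
            if rng.random() < _miss_prob(img_box, rig, model):
                continue
            if plant.plant_class == SUGAR_BEET:
                if rng.random() < model.beet_as_potato_prob:
                    cls, crange = POTATO, model.misclass_confidence_range
                else:
                    cls, crange = SUGAR_BEET, model.plant_confidence_range
                box = _jittered_image_box(img_box, rig, model.box_jitter_sigma_m, rng)
                dets[fid].append(DetectionEvent(fid, cls, conf(crange), box))
                continue
            # potato observation
            if rng.random() < model.split_prob and img_box.width >= 8:
                # one plant reported as two smaller boxes (split along the
                # wider image axis)
                if img_box.width >= img_box.height:
                    parts = [
                        BoundingBox(img_box.x_min, img_box.y_min,
                                    img_box.width * 0.45, img_box.height, IMAGE),
                        BoundingBox(img_box.x_min + img_box.width * 0.55,
                                    img_box.y_min, img_box.width * 0.45,
                                    img_box.height, IMAGE),
                    ]
                else:
                    parts = [
                        BoundingBox(img_box.x_min, img_box.y_min, img_box.width,
                                    img_box.height * 0.45, IMAGE),
                        BoundingBox(img_box.x_min,
                                    img_box.y_min + img_box.height * 0.55,
                                    img_box.width, img_box.height * 0.45, IMAGE),
                    ]
                for part in parts:
                    box = _jittered_image_box(part, rig, model.box_jitter_sigma_m, rng)
                    dets[fid].append(DetectionEvent(
                        fid, POTATO, conf(model.plant_confidence_range), box))
            else:
                box = _jittered_image_box(img_box, rig, model.box_jitter_sigma_m, rng)
                dets[fid].append(DetectionEvent(
                    fid, POTATO, conf(model.plant_confidence_range), box))

    # merge nearby same-frame potato boxes into one (adjacent plants fused)
    if model.merge_prob > 0:
        merge_px = model.merge_distance_m / rig.scale_along
        for fid in sorted(dets):
            frame_dets = dets[fid]
            pot_idx = [i for i, d in enumerate(frame_dets)
                       if d.det_class == POTATO]
            dead: set[int] = set()
            merged: list[DetectionEvent] = []
            for a_pos, i in enumerate(pot_idx):
                if i in dead:
                    continue
                for j in pot_idx[a_pos + 1:]:
                    if j in dead:
                        continue
                    ci, cj = frame_dets[i].box.center, frame_dets[j].box.center
                    if math.hypot(ci[0] - cj[0], ci[1] - cj[1]) > merge_px:
                        continue
                    if rng.random() < model.merge_prob:
                        union = frame_dets[i].box.union_with(frame_dets[j].box)
                        c = max(frame_dets[i].confidence, frame_dets[j].confidence)
                        merged.append(DetectionEvent(fid, POTATO, c, union))
                        dead.update((i, j))
                        break
            if dead:
                dets[fid] = [d for k, d in enumerate(frame_dets)
                             if k not in dead] + merged

    # background objects (small weeds, rocks) as a spatial Poisson process
    rate = model.background_fp_rate_per_m2
    if ps.plot.soil_type == "peaty":
        rate *= model.peaty_rate_multiplier
    area = ps.plot.length_m * ps.plot.width_m
    n_bg = int(rng.poisson(rate * area))
    cfgp = ps.plot
    for _ in range(n_bg):
        size = rng.uniform(0.04, 0.10)
        cx = ps.along_offset_m + rng.uniform(0.0, cfgp.length_m)
        cy = rng.uniform(0.4, 0.4 + cfgp.width_m)
        wb = BoundingBox(cx - size / 2, cy - size / 2, size, size, WORLD)
        ps.background_boxes.append(wb)
        for fid in sorted(ps.frames):
            clipped = _clip_to_footprint(wb, ps.frames[fid], rig, 0.5)
            if clipped is None:
                continue
            if rng.random() < model.background_miss_prob:
                continue
            img_box = world_to_image(clipped, ps.frames[fid], rig)
            box = _jittered_image_box(img_box, rig, model.box_jitter_sigma_m, rng)
            dets[fid].append(DetectionEvent(
                fid, POTATO, conf(model.background_confidence_range), box))

    return dets


def generate_detections(
    scene: Scene, model: ErrorModel, seed: int | None = None
) -> dict[str, list[DetectionEvent]]:
    """Simulate raw detector output for every frame of a scene.

    Returns the *unfiltered* detection pool; run the post-processing chain
    (confidence filter, then class-wise NMS) before evaluation, exactly as
    an inference pipeline would.
    """
    if seed is None:
        seed = scene.config.seed
    out: dict[str, list[DetectionEvent]] = {}
    for ps in scene.plot_scenes:
        ps.background_boxes = []
        rng = _plot_rng(seed, ps.plot.plot_id, 1)
        out.update(_detections_for_plot(ps, scene.rig, model, rng))
    return out
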