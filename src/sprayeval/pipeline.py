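"""End-to-end pipeline: generate, post-process, evaluate, simulate, report.

The stages mirror the physical system: the generator stands in for the
camera rig plus detector, post-processing mirrors the inference server
(confidence filter, class-wise NMS), the three evaluation tiers score the
same detections at image, plant and field level, and every report embeds
the fully resolved configuration and seed for auditability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .application_eval import (
    ApplicationReport,
    cluster_plants,
    evaluate_application,
)
from .config import RunConfig
from .formats import (
    dump_json,
    read_coco_gt,
    read_yolo_detections,
    write_coco_gt,
    write_manifest,
    write_yolo_detections,
)
from .image_eval import GroundTruthBox, ImageLevelReport, evaluate_image_level
from .postprocess import DetectionEvent, confidence_filter, nms
from .scene import CameraRig, Frame, Plant, POTATO, image_to_world
from .sprayer import FieldReport, SprayMap, plan_spray, score_field
from .synthetic import Scene, generate_detections, generate_scene

__all__ = [
    "PipelineError",
    "MissingInputError",
    "SchemaError",
    "PipelineResult",
    "postprocess_detections",
    "run_in_memory",
    "run_pipeline",
]

MODES = ("generate", "eval-image", "eval-application", "simulate-spray", "all")


class PipelineError(RuntimeError):
    exit_code = 1


class MissingInputError(PipelineError):
    exit_code = 3


class SchemaError(PipelineError):
    exit_code = 4


class GeometryError(PipelineError):
    exit_code = 5


def postprocess_detections(
    dets_by_frame: dict[str, list[DetectionEvent]], config: RunConfig
) -> dict[str, list[DetectionEvent]]:
    """Confidence filter then class-wise NMS, per frame."""
    t = config.thresholds
    return {
        fid: nms(confidence_filter(dets, t.confidence), t.nms_iou)
        for fid, dets in dets_by_frame.items()
    }


def _plot_of_plant(
    plants: list[Plant], plot_of_frame: dict[str, int]
) -> dict[str, int]:
    return {
        p.plant_id: plot_of_frame.get(p.observations[0][0], -1) if p.observations
        else -1
        for p in plants
    }


@dataclass
class PipelineResult:
    scene: Scene | None
    dets_post: dict[str, list[DetectionEvent]]
    plants: list[Plant]
    image_report: ImageLevelReport
    application_report: ApplicationReport
    spray_map: SprayMap
    field_report: FieldReport


def _evaluate(
    gts_by_frame: dict[str, list[GroundTruthBox]],
    dets_post: dict[str, list[DetectionEvent]],
    frames: dict[str, Frame],
    rig: CameraRig,
    plot_of_frame: dict[str, int],
    config: RunConfig,
    scene: Scene | None = None,
) -> PipelineResult:
    t = config.thresholds
    image_report = evaluate_image_level(
        gts_by_frame, dets_post, plot_of_frame, t.match_iou
    )
    plants = cluster_plants(gts_by_frame, frames, rig, t.link_radius_m)
    plot_of_plant = _plot_of_plant(plants, plot_of_frame)
    app_report = evaluate_application(
        plants, dets_post, frames, rig,
        plot_of_frame=plot_of_frame, plot_of_plant=plot_of_plant,
        coverage_threshold=t.coverage, cluster_radius=t.cluster_radius_m,
        confidence_threshold=t.confidence,
        dedupe_background=config.dedupe_background,
    )
    potato_world = [
        image_to_world(d.box, frames[fid], rig)
        for fid, dets in dets_post.items()
        for d in dets
        if d.det_class == POTATO
    ]
    spray = plan_spray(potato_world, config.nozzles, t.speed_mps)
    field_report = score_field(
        spray, plants, config.nozzles, t.hit_margin_m, t.near_radius_m,
        plot_of_plant,
    )
    return PipelineResult(
        scene=scene, dets_post=dets_post, plants=plants,
        image_report=image_report, application_report=app_report,
        spray_map=spray, field_report=field_report,
    )


def run_in_memory(config: RunConfig) -> PipelineResult:
    """Generate a synthetic trial and run all three evaluation tiers."""
    scene = generate_scene(config.scenario())
    raw = generate_detections(scene, config.error_model, config.seed)
    dets_post = postprocess_detections(raw, config)
    return _evaluate(
        scene.gts_by_frame, dets_post, scene.frames, scene.rig,
        scene.plot_of_frame, config, scene,
    )


# ---------------------------------------------------------------- file I/O

def _write_scene(scene: Scene, raw_dets, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_coco_gt(
        out / "ground_truth.json", scene.gts_by_frame, scene.frames, scene.rig,
        scene.plot_of_frame,
    )
    write_yolo_detections(out / "detections", raw_dets, scene.rig)
    rows = []
    for ps in scene.plot_scenes:
        n_beet = sum(
            sum(1 for g in gts if g.gt_class == "sugar_beet")
            for gts in ps.gts_by_frame.values()
        )
        n_pot = sum(
            sum(1 for g in gts if g.gt_class == "potato")
            for gts in ps.gts_by_frame.values()
        )
        rig = scene.rig
        rows.append({
            "part": ps.plot.plot_id,
            "acquisition_date": "synthetic",
            "contains_barley": "Yes" if ps.plot.contains_barley else "No",
            "lighting": "Controlled",
            "resolution": f"{rig.image_width_px} x {rig.image_height_px}",
            "n_images": len(ps.frames),
            "n_beet_annotations": n_beet,
            "n_potato_annotations": n_pot,
        })
    write_manifest(out / "manifest.csv", rows)


def _load_inputs(out: Path, config: RunConfig):
    gt_path = out / "ground_truth.json"
    det_dir = out / "detections"
    if not gt_path.exists():
        raise MissingInputError(f"ground truth not found: {gt_path}")
    if not det_dir.is_dir():
        raise MissingInputError(f"detections directory not found: {det_dir}")
    try:
        gts, frames, rig, plot_of_frame = read_coco_gt(gt_path)
    except (KeyError, ValueError, TypeError) as e:
        raise SchemaError(f"malformed ground truth {gt_path}: {e}") from e
    if (rig.image_width_px != config.rig.image_width_px
            or rig.image_height_px != config.rig.image_height_px):
        raise GeometryError(
            f"rig in {gt_path} ({rig.image_width_px}x{rig.image_height_px}) "
            f"does not match configured rig"
        )
    try:
        dets = read_yolo_detections(det_dir, rig)
    except (KeyError, ValueError) as e:
        raise SchemaError(f"malformed detections in {det_dir}: {e}") from e
    unknown = set(dets) - set(frames)
    if unknown:
        raise SchemaError(
            f"detections for unknown frames: {sorted(unknown)[:5]}"
        )
    return gts, dets, frames, rig, plot_of_frame


def _csv_writerows(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def _write_reports(res: PipelineResult, config: RunConfig, out: Path,
                   stages: list[str]) -> None:
    meta = {"config": config.as_dict(), "seed": config.seed}
    if "eval-image" in stages:
        doc = res.image_report.as_dict()
        doc.update(meta)
        dump_json(doc, out / "image_report.json")
        rows = [
            [plot, cls, c.tp, c.fp, c.fn,
             "undefined" if c.precision is None else repr(c.precision),
             "undefined" if c.recall is None else repr(c.recall)]
            for (plot, cls), c in sorted(res.image_report.per_plot.items())
        ]
        _csv_writerows(
            out / "image_report.csv",
            ["plot_id", "class", "tp", "fp", "fn", "precision", "recall"], rows,
        )
    if "eval-application" in stages:
        doc = res.application_report.as_dict()
        doc.update(meta)
        dump_json(doc, out / "application_report.json")
        rows = []
        for plot, c in sorted(res.application_report.per_plot.items()):
            r = c.potato_recall
            rows.append([
                plot, c.potato_tp, c.potato_fn, c.beet_fp, c.background_fp,
                "undefined" if r is None else repr(r),
            ])
        _csv_writerows(
            out / "application_report.csv",
            ["plot_id", "potato_tp", "potato_fn", "beet_fp", "background_fp",
             "potato_recall"], rows,
        )
        (out / "application_audit.log").write_text(
            "\n".join(res.application_report.audit_lines()) + "\n",
            encoding="utf-8",
        )
    if "simulate-spray" in stages:
        doc = res.field_report.as_dict()
        doc.update(meta)
        dump_json(doc, out / "field_report.json")
        _csv_writerows(
            out / "spray_map.csv", ["nozzle", "x_start", "x_end"],
            [[i, repr(x0), repr(x1)] for i, (x0, x1) in res.spray_map.activations],
        )
        # BED-like per-nozzle intervals (micrometre integer coordinates)
        bed_lines = [
            f"nozzle_{i:02d}\t{round(x0 * 1e6)}\t{round(x1 * 1e6)}"
            for i, (x0, x1) in res.spray_map.activations
        ]
        (out / "spray_map.bed").write_text(
            "\n".join(bed_lines) + ("\n" if bed_lines else ""), encoding="utf-8"
        )
        rows = []
        for plot, c in sorted(res.field_report.per_plot.items()):
            rows.append([
                plot, c.potatoes_total, c.potatoes_sprayed, c.beets_total,
                c.beets_hit, c.beets_hit_near_potato,
            ])
        _csv_writerows(
            out / "field_report.csv",
            ["plot_id", "potatoes_total", "potatoes_sprayed", "beets_total",
             "beets_hit", "beets_hit_near_potato"], rows,
        )


def run_pipeline(config: RunConfig, mode: str, out_dir: str | Path) -> PipelineResult:
    """Execute the requested stages in dependency order, writing reports.

    ``generate`` writes ground truth, raw detections and the plot manifest;
    the evaluation stages read those files back (so on-disk and in-memory
    routes agree exactly) and write their reports into the same directory.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = None
    if mode in ("generate", "all"):
        scene = generate_scene(config.scenario())
        raw = generate_detections(scene, config.error_model, config.seed)
        _write_scene(scene, raw, out)
        if mode == "generate":
            return PipelineResult(
                scene, {}, [], None, None, SprayMap(), None  # type: ignore[arg-type]
            )
    gts, raw, frames, rig, plot_of_frame = _load_inputs(out, config)
    dets_post = postprocess_detections(raw, config)
    res = _evaluate(gts, dets_post, frames, rig, plot_of_frame, config, scene)
    stages = (
        ["eval-image", "eval-application", "simulate-spray"]
        if mode == "all" else [mode]
    )
    _write_reports(res, config, out, stages)
    return res
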