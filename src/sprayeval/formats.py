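"""File formats: COCO-style ground truth, YOLO-style detections, manifests.

Ground truth travels as COCO-style JSON (images / annotations / categories)
with the acquisition geometry embedded: each image record carries its
camera, trigger and world anchor, and the file's ``info`` block carries the
rig, so a ground-truth file is self-sufficient for world-frame evaluation.
Detections travel as YOLO-style text, one file per frame, each line
``class_id x_center y_center width height confidence`` with coordinates
normalized to the image size.  Class ids: 0 = sugar_beet, 1 = potato.

All outputs are UTF-8 with POSIX newlines, fixed column orders and
full-precision floats, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .image_eval import GroundTruthBox
from .postprocess import DetectionEvent
from .scene import BoundingBox, CameraRig, Frame, IMAGE, POTATO, SUGAR_BEET

__all__ = [
    "CLASS_IDS",
    "CLASS_NAMES",
    "write_coco_gt",
    "read_coco_gt",
    "write_yolo_detections",
    "read_yolo_detections",
    "write_manifest",
    "read_manifest",
    "summarize_manifest",
    "dump_json",
]

CLASS_IDS = {SUGAR_BEET: 0, POTATO: 1}
CLASS_NAMES = {v: k for k, v in CLASS_IDS.items()}

MANIFEST_COLUMNS = [
    "part", "acquisition_date", "contains_barley", "lighting", "resolution",
    "n_images", "n_beet_annotations", "n_potato_annotations",
]


def dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def write_coco_gt(
    path: str | Path,
    gts_by_frame: dict[str, list[GroundTruthBox]],
    frames: dict[str, Frame],
    rig: CameraRig,
    plot_of_frame: dict[str, int] | None = None,
) -> None:
    """Write ground truth with embedded rig and frame geometry."""
    images = []
    frame_num = {fid: i + 1 for i, fid in enumerate(sorted(frames))}
    for fid in sorted(frames):
        f = frames[fid]
        rec = {
            "id": frame_num[fid],
            "file_name": f"{fid}.png",
            "width": rig.image_width_px,
            "height": rig.image_height_px,
            "frame_id": fid,
            "camera_index": f.camera_index,
            "trigger_index": f.trigger_index,
            "world_anchor": [f.world_anchor[0], f.world_anchor[1]],
        }
        if plot_of_frame is not None:
            rec["plot_id"] = plot_of_frame[fid]
        images.append(rec)
    annotations = []
    for fid in sorted(gts_by_frame):
        for gt in gts_by_frame[fid]:
            b = gt.box
            annotations.append({
                "id": len(annotations) + 1,
                "image_id": frame_num[fid],
                "category_id": CLASS_IDS[gt.gt_class],
                "bbox": [b.x_min, b.y_min, b.width, b.height],
                "area": b.area,
                "iscrowd": 0,
                "plant_id": gt.plant_id,
            })
    doc = {
        "info": {
            "description": "crop/weed ground truth with acquisition geometry",
            "rig": {
                "fov_along_track": rig.fov_along_track,
                "fov_across_track": rig.fov_across_track,
                "trigger_spacing": rig.trigger_spacing,
                "image_width_px": rig.image_width_px,
                "image_height_px": rig.image_height_px,
                "n_cameras": rig.n_cameras,
                "camera_offsets_across_track": list(
                    rig.camera_offsets_across_track
                ),
            },
        },
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": i, "name": name} for i, name in sorted(CLASS_NAMES.items())
        ],
    }
    dump_json(doc, path)


def read_coco_gt(
    path: str | Path,
) -> tuple[dict[str, list[GroundTruthBox]], dict[str, Frame], CameraRig,
           dict[str, int]]:
    """Read ground truth; returns (gts_by_frame, frames, rig, plot_of_frame)."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    r = doc["info"]["rig"]
    rig = CameraRig(
        fov_along_track=r["fov_along_track"],
        fov_across_track=r["fov_across_track"],
        trigger_spacing=r["trigger_spacing"],
        image_width_px=r["image_width_px"],
        image_height_px=r["image_height_px"],
        n_cameras=r["n_cameras"],
        camera_offsets_across_track=tuple(r["camera_offsets_across_track"]),
    )
    cat_names = {c["id"]: c["name"] for c in doc["categories"]}
    frames: dict[str, Frame] = {}
    fid_of_num: dict[int, str] = {}
    plot_of_frame: dict[str, int] = {}
    for rec in doc["images"]:
        fid = rec.get("frame_id", rec["file_name"].rsplit(".", 1)[0])
        frames[fid] = Frame(
            fid, rec["camera_index"], rec["trigger_index"],
            (rec["world_anchor"][0], rec["world_anchor"][1]),
        )
        fid_of_num[rec["id"]] = fid
        if "plot_id" in rec:
            plot_of_frame[fid] = rec["plot_id"]
    gts: dict[str, list[GroundTruthBox]] = {fid: [] for fid in frames}
    for ann in doc["annotations"]:
        fid = fid_of_num[ann["image_id"]]
        x, y, w, h = ann["bbox"]
        gts[fid].append(GroundTruthBox(
            fid, cat_names[ann["category_id"]],
            BoundingBox(x, y, w, h, IMAGE), ann.get("plant_id"),
        ))
    return gts, frames, rig, plot_of_frame


def write_yolo_detections(
    out_dir: str | Path,
    dets_by_frame: dict[str, list[DetectionEvent]],
    rig: CameraRig,
) -> None:
    """One text file per frame: ``class xc yc w h conf`` (normalized)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    W, H = rig.image_width_px, rig.image_height_px
    for fid in sorted(dets_by_frame):
        lines = []
        for d in dets_by_frame[fid]:
            cx, cy = d.box.center
            lines.append(
                f"{CLASS_IDS[d.det_class]} {cx / W!r} {cy / H!r} "
                f"{d.box.width / W!r} {d.box.height / H!r} {d.confidence!r}"
            )
        (out / f"{fid}.txt").write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
        )


def read_yolo_detections(
    in_dir: str | Path, rig: CameraRig
) -> dict[str, list[DetectionEvent]]:
    W, H = rig.image_width_px, rig.image_height_px
    out: dict[str, list[DetectionEvent]] = {}
    for path in sorted(Path(in_dir).glob("*.txt")):
        fid = path.stem
        dets: list[DetectionEvent] = []
        for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 fields, got {len(parts)}")
            cls = CLASS_NAMES[int(parts[0])]
            xc, yc, w, h, conf = map(float, parts[1:])
            dets.append(DetectionEvent(
                fid, cls, conf,
                BoundingBox((xc - w / 2) * W, (yc - h / 2) * H, w * W, h * H, IMAGE),
            ))
        out[fid] = dets
    return out


def write_manifest(path: str | Path, rows: list[dict]) -> None:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    for i, row in df.iterrows():
        for col in ("n_images", "n_beet_annotations", "n_potato_annotations"):
            v = row[col]
            if pd.isna(v) or int(v) < 0 or int(v) != v:
                raise ValueError(f"manifest row {i + 1}: bad count {col}={v!r}")
    return df


def summarize_manifest(manifest: pd.DataFrame) -> tuple[int, int, int]:
    """Exact column totals: (n_images, n_beet, n_potato)."""
    return (
        int(manifest["n_images"].sum()),
        int(manifest["n_beet_annotations"].sum()),
        int(manifest["n_potato_annotations"].sum()),
    )
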