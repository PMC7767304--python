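"""Plant-level ("application-level") evaluation over overlapping frames.

With ~50% or more frame overlap along the driving direction a plant is seen
up to three times, and the sprayer triggers greedily on the first potato
detection.  Image-level metrics therefore misjudge the system: a plant
missed in two views but caught in the third is sprayed correctly, a single
box over two adjacent potatoes sprays both, a plant split into two boxes is
sprayed once.  This module scores detections per *plant*, not per box:

* a potato with at least one associated potato detection in any frame is one
  true positive (TP), no matter how many views or boxes supported it;
* a potato never associated with any potato detection is one false negative;
* a sugar beet associated with one or more potato detections is one crop
  false positive (it would be sprayed and terminated), counted once;
* a potato detection covering k potatoes yields k TPs; one overlapping k
  beets yields k crop FPs;
* potato detections associated with no plant are background false positives
  (wasted herbicide, no crop damage); repeated sightings of the same
  background object across overlapping frames are merged by single-linkage
  clustering of their world centroids, one FP per cluster.

Sugar-beet-class detections never trigger the sprayer and are ignored here.

A detection "covers" a plant when the intersection with the plant's world
box is at least ``coverage_threshold`` of the plant box area, or when the
plant centre lies inside the detection — accepting both full enclosures and
partial split boxes while rejecting grazing overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .image_eval import GroundTruthBox, precision_recall
from .postprocess import DetectionEvent
from .scene import (
    BoundingBox,
    CameraRig,
    Frame,
    Plant,
    POTATO,
    SUGAR_BEET,
    WORLD,
    image_to_world,
)

__all__ = [
    "DEFAULT_LINK_RADIUS",
    "DEFAULT_COVERAGE_THRESHOLD",
    "PlantVerdict",
    "BackgroundFPCluster",
    "PlotApplicationCounts",
    "ApplicationReport",
    "cluster_plants",
    "associate",
    "cluster_background_fps",
    "evaluate_application",
]

#: World-distance linking radius for merging per-frame ground truths into one
#: plant: half the 0.19 m intra-row sowing distance, so adjacent beets are
#: never fused while projection jitter is absorbed.
DEFAULT_LINK_RADIUS = 0.09
#: Minimum intersection / plant-box-area ratio for a detection to cover a plant.
DEFAULT_COVERAGE_THRESHOLD = 0.25


@dataclass
class PlantVerdict:
    """The single plant-level outcome for one plant."""

    plant_id: str
    plant_class: str
    verdict: str  # "TP" | "FN" for potatoes, "FP_crop" for hit beets
    supporting_detections: list[DetectionEvent] = field(default_factory=list)


@dataclass
class BackgroundFPCluster:
    cluster_id: int
    world_centroid: tuple[float, float]
    member_detections: list[DetectionEvent] = field(default_factory=list)


def _single_linkage(points: np.ndarray, radius: float) -> np.ndarray:
    """Component label per point under single-linkage at ``radius``."""
    n = len(points)
    if n == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def cluster_plants(
    gts_by_frame: dict[str, list[GroundTruthBox]],
    frames: dict[str, Frame],
    rig: CameraRig,
    link_radius: float = DEFAULT_LINK_RADIUS,
) -> list[Plant]:
    """Merge per-frame ground-truth boxes into world-level plants.

    Annotations are projected to world coordinates; boxes of the same class
    whose centres fall within ``link_radius`` of each other (single linkage)
    are one plant.  The plant's world box is the envelope of its projected
    observation boxes — clipped edge views extend it less than full views.
    """
    entries: list[tuple[GroundTruthBox, BoundingBox]] = []
    for fid, gts in gts_by_frame.items():
        frame = frames[fid]
        for gt in gts:
            entries.append((gt, image_to_world(gt.box, frame, rig)))

    plants: list[Plant] = []
    for cls in (POTATO, SUGAR_BEET):
        sub = [(gt, wb) for gt, wb in entries if gt.gt_class == cls]
        if not sub:
            continue
        centers = np.array([wb.center for _, wb in sub])
        labels = _single_linkage(centers, link_radius)
        for lab in np.unique(labels):
            members = [sub[i] for i in np.flatnonzero(labels == lab)]
            world_box = members[0][1]
            for _, wb in members[1:]:
                world_box = world_box.union_with(wb)
            plants.append(
                Plant(
                    plant_id=f"{cls}_{len(plants):05d}",
                    plant_class=cls,
                    world_box=world_box,
                    observations=[(gt.frame_id, gt.box) for gt, _ in members],
                )
            )
    return plants


def associate(
    det_world_box: BoundingBox,
    plants: list[Plant],
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> list[str]:
    """Ids of every plant (any class) the world-projected detection covers."""
    if det_world_box.frame != WORLD:
        raise ValueError("detection box must be world-projected")
    hits = []
    for plant in plants:
        inter = det_world_box.intersection_area(plant.world_box)
        if inter <= 0:
            continue
        cx, cy = plant.world_box.center
        if (inter / plant.world_box.area >= coverage_threshold
                or det_world_box.contains_point(cx, cy)):
            hits.append(plant.plant_id)
    return hits


def cluster_background_fps(
    dets_world: list[tuple[DetectionEvent, BoundingBox]],
    cluster_radius: float = DEFAULT_LINK_RADIUS,
) -> list[BackgroundFPCluster]:
    """Single-linkage clustering of unassociated detections by world centroid."""
    if not dets_world:
        return []
    centers = np.array([wb.center for _, wb in dets_world])
    labels = _single_linkage(centers, cluster_radius)
    clusters = []
    for lab in sorted(np.unique(labels)):
        idx = np.flatnonzero(labels == lab)
        centroid = centers[idx].mean(axis=0)
        clusters.append(
            BackgroundFPCluster(
                cluster_id=int(lab),
                world_centroid=(float(centroid[0]), float(centroid[1])),
                member_detections=[dets_world[i][0] for i in idx],
            )
        )
    return clusters


@dataclass
class PlotApplicationCounts:
    potato_tp: int = 0
    potato_fn: int = 0
    beet_fp: int = 0
    background_fp: int = 0

    @property
    def potato_recall(self) -> float | None:
        return precision_recall(self.potato_tp, 0, self.potato_fn)[1]

    def composition(self) -> dict[str, float] | None:
        """Share of detection units that hit a potato / a beet / background."""
        total = self.potato_tp + self.beet_fp + self.background_fp
        if total == 0:
            return None
        return {
            "potato": self.potato_tp / total,
            "sugar_beet": self.beet_fp / total,
            "background": self.background_fp / total,
        }

    def add(self, other: "PlotApplicationCounts") -> None:
        self.potato_tp += other.potato_tp
        self.potato_fn += other.potato_fn
        self.beet_fp += other.beet_fp
        self.background_fp += other.background_fp


@dataclass
class ApplicationReport:
    per_plot: dict[int, PlotApplicationCounts]
    pooled: PlotApplicationCounts
    verdicts: list[PlantVerdict]
    background_clusters: list[BackgroundFPCluster]
    params: dict

    def as_dict(self) -> dict:
        def row(c: PlotApplicationCounts) -> dict:
            r = c.potato_recall
            comp = c.composition()
            return {
                "potato_tp": c.potato_tp,
                "potato_fn": c.potato_fn,
                "beet_fp": c.beet_fp,
                "background_fp": c.background_fp,
                "potato_recall": "undefined" if r is None else r,
                "composition": comp if comp is not None else "undefined",
            }

        return {
            "level": "application",
            "params": self.params,
            "per_plot": {str(p): row(c) for p, c in sorted(self.per_plot.items())},
            "pooled": row(self.pooled),
        }

    def audit_lines(self) -> list[str]:
        """Human-readable per-plant audit of every verdict."""
        lines = []
        for v in self.verdicts:
            lines.append(f"{v.plant_id} [{v.plant_class}] -> {v.verdict}")
            for d in v.supporting_detections:
                b = d.box
                lines.append(
                    f"    {d.frame_id} conf={d.confidence:.3f} "
                    f"box=({b.x_min:.1f},{b.y_min:.1f},{b.width:.1f},{b.height:.1f})"
                )
        for c in self.background_clusters:
            cx, cy = c.world_centroid
            lines.append(
                f"background_fp_{c.cluster_id:04d} at ({cx:.3f},{cy:.3f}) m "
                f"-> FP_background ({len(c.member_detections)} sightings)"
            )
        return lines


def evaluate_application(
    plants: list[Plant],
    dets_by_frame: dict[str, list[DetectionEvent]],
    frames: dict[str, Frame],
    rig: CameraRig,
    plot_of_frame: dict[str, int] | None = None,
    plot_of_plant: dict[str, int] | None = None,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    cluster_radius: float = DEFAULT_LINK_RADIUS,
    confidence_threshold: float = 0.001,
    dedupe_background: bool = True,
) -> ApplicationReport:
    """Score plants against potato-class detections across all frames.

    ``dets_by_frame`` must already be post-processed (confidence filter +
    NMS); detections below ``confidence_threshold`` are rejected as evidence
    of a raw pool.  Every plant receives exactly one verdict; potatoes are TP
    or FN, beets FP_crop or nothing.  When plot assignments are given the
    counts are also reported per plot.
    """
    potato_dets: list[tuple[DetectionEvent, BoundingBox]] = []
    for fid, dets in dets_by_frame.items():
        for d in dets:
            if d.confidence < confidence_threshold:
                raise ValueError(
                    f"detection with confidence {d.confidence} below the filter "
                    f"threshold {confidence_threshold}: post-process first"
                )
            if d.det_class != POTATO:
                continue  # beet-class detections never trigger the sprayer
            potato_dets.append((d, image_to_world(d.box, frames[fid], rig)))

    supporting: dict[str, list[DetectionEvent]] = {p.plant_id: [] for p in plants}
    background: list[tuple[DetectionEvent, BoundingBox]] = []
    for det, wbox in potato_dets:
        hit_ids = associate(wbox, plants, coverage_threshold)
        if hit_ids:
            for pid in hit_ids:
                supporting[pid].append(det)
        else:
            background.append((det, wbox))

    verdicts: list[PlantVerdict] = []
    for p in plants:
        sup = supporting[p.plant_id]
        if p.plant_class == POTATO:
            verdict = "TP" if sup else "FN"
        else:
            if not sup:
                continue  # an undetected beet contributes nothing
            verdict = "FP_crop"
        verdicts.append(PlantVerdict(p.plant_id, p.plant_class, verdict, sup))

    if dedupe_background:
        clusters = cluster_background_fps(background, cluster_radius)
    else:
        clusters = [
            BackgroundFPCluster(i, wb.center, [d])
            for i, (d, wb) in enumerate(background)
        ]

    def plot_of(plant_id: str) -> int:
        return plot_of_plant.get(plant_id, -1) if plot_of_plant else -1

    per_plot: dict[int, PlotApplicationCounts] = {}
    pooled = PlotApplicationCounts()
    for v in verdicts:
        c = per_plot.setdefault(plot_of(v.plant_id), PlotApplicationCounts())
        if v.verdict == "TP":
            c.potato_tp += 1
            pooled.potato_tp += 1
        elif v.verdict == "FN":
            c.potato_fn += 1
            pooled.potato_fn += 1
        else:
            c.beet_fp += 1
            pooled.beet_fp += 1
    for cl in clusters:
        pooled.background_fp += 1
        if plot_of_frame:
            plot = plot_of_frame.get(cl.member_detections[0].frame_id, -1)
        else:
            plot = -1
        per_plot.setdefault(plot, PlotApplicationCounts()).background_fp += 1

    params = {
        "coverage_threshold": coverage_threshold,
        "cluster_radius": cluster_radius,
        "confidence_threshold": confidence_threshold,
        "dedupe_background": dedupe_background,
    }
    return ApplicationReport(per_plot=per_plot, pooled=pooled, verdicts=verdicts,
                             background_clusters=clusters, params=params)
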