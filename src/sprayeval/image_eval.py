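"""Conventional image-level evaluation: IoU matching and precision/recall.

A detection is a true positive when it can be matched one-to-one to a
ground-truth box of the same class with IoU strictly greater than the
threshold (default 0.5).  Matching is greedy by descending detection
confidence, each detection taking the free ground truth with the highest
IoU — the convention of the common object-detection toolkits.  Unmatched
detections are false positives, unmatched ground truths false negatives;
precision = TP/(TP+FP) and recall = TP/(TP+FN).

Per-plot metrics are computed from per-plot pooled counts, never by
averaging per-image ratios.  A zero denominator yields the ``None``
sentinel (serialized as ``"undefined"``) and is excluded from averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .postprocess import DetectionEvent, iou
from .scene import BoundingBox, POTATO, SUGAR_BEET

__all__ = [
    "GroundTruthBox",
    "MatchResult",
    "ClassCounts",
    "ImageLevelReport",
    "match_image",
    "precision_recall",
    "evaluate_image_level",
]

DEFAULT_MATCH_IOU = 0.5


@dataclass(frozen=True)
class GroundTruthBox:
    """One ground-truth annotation in one frame."""

    frame_id: str
    gt_class: str
    box: BoundingBox
    plant_id: str | None = None  # carried through from generators; unused here


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[DetectionEvent, GroundTruthBox]] = field(
        default_factory=list
    )


def match_image(
    gts: list[GroundTruthBox],
    dets: list[DetectionEvent],
    iou_threshold: float = DEFAULT_MATCH_IOU,
) -> MatchResult:
    """One-to-one class-aware matching of detections to ground truths.

    Greedy by descending confidence; a pair matches only when same class and
    IoU > ``iou_threshold``.  ``tp + fn`` equals the number of ground truths.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    taken = [False] * len(gts)
    pairs: list[tuple[DetectionEvent, GroundTruthBox]] = []
    for i in order:
        det = dets[i]
        best_j, best_iou = -1, iou_threshold
        for j, gt in enumerate(gts):
            if taken[j] or gt.gt_class != det.det_class:
                continue
            v = iou(det.box, gt.box)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            pairs.append((det, gts[best_j]))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(dets) - tp, fn=len(gts) - tp,
                       matched_pairs=pairs)


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float | None, float | None]:
    """Precision and recall from counts; ``None`` on a zero denominator."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    return precision, recall


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def add(self, other: "MatchResult | ClassCounts") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn

    @property
    def precision(self) -> float | None:
        return precision_recall(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float | None:
        return precision_recall(self.tp, self.fp, self.fn)[1]


@dataclass
class ImageLevelReport:
    """TP/FP/FN and precision/recall per (plot, class) and pooled per class."""

    per_plot: dict[tuple[int, str], ClassCounts]
    pooled: dict[str, ClassCounts]
    iou_threshold: float

    def as_dict(self) -> dict:
        def row(c: ClassCounts) -> dict:
            p, r = c.precision, c.recall
            return {
                "tp": c.tp, "fp": c.fp, "fn": c.fn,
                "precision": "undefined" if p is None else p,
                "recall": "undefined" if r is None else r,
            }

        return {
            "level": "image",
            "iou_threshold": self.iou_threshold,
            "per_plot": {
                f"{plot}/{cls}": row(c)
                for (plot, cls), c in sorted(self.per_plot.items())
            },
            "pooled": {cls: row(c) for cls, c in sorted(self.pooled.items())},
        }


def evaluate_image_level(
    gts_by_frame: dict[str, list[GroundTruthBox]],
    dets_by_frame: dict[str, list[DetectionEvent]],
    plot_of_frame: dict[str, int],
    iou_threshold: float = DEFAULT_MATCH_IOU,
) -> ImageLevelReport:
    """Match every frame independently and pool counts per plot and overall."""
    per_plot: dict[tuple[int, str], ClassCounts] = {}
    pooled: dict[str, ClassCounts] = {POTATO: ClassCounts(), SUGAR_BEET: ClassCounts()}
    frames = sorted(set(gts_by_frame) | set(dets_by_frame))
    for fid in frames:
        plot = plot_of_frame[fid]
        gts = gts_by_frame.get(fid, [])
        dets = dets_by_frame.get(fid, [])
        for cls in (POTATO, SUGAR_BEET):
            res = match_image(
                [g for g in gts if g.gt_class == cls],
                [d for d in dets if d.det_class == cls],
                iou_threshold,
            )
            per_plot.setdefault((plot, cls), ClassCounts()).add(res)
            pooled[cls].add(res)
    return ImageLevelReport(per_plot=per_plot, pooled=pooled,
                            iou_threshold=iou_threshold)
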