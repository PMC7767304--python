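"""Detector output post-processing: confidence filtering and class-wise NMS.

Mirrors the inference-side pipeline of a single-stage detector: the raw
detection pool is first thresholded on object confidence (objectness times
class confidence, default threshold 0.001) and then pruned by greedy
non-maximum suppression at IoU 0.5, applied per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .scene import BoundingBox, POTATO, SUGAR_BEET

__all__ = ["DetectionEvent", "iou", "confidence_filter", "nms"]

#: Confidence below which raw detections are discarded.
DEFAULT_CONFIDENCE_THRESHOLD = 0.001
#: IoU above which a lower-confidence same-class detection is suppressed.
DEFAULT_NMS_IOU = 0.5


@dataclass(frozen=True)
class DetectionEvent:
    """One detector output: class, confidence and box in one frame."""

    frame_id: str
    det_class: str
    confidence: float
    box: BoundingBox

    def __post_init__(self) -> None:
        if self.det_class not in (SUGAR_BEET, POTATO):
            raise ValueError(f"detection class must be sugar_beet or potato, "
                             f"got {self.det_class!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes in the same reference frame.

    Symmetric, in [0, 1], and 1 exactly when the boxes coincide.  Degenerate
    (zero-area) overlap yields 0.
    """
    if a.frame != b.frame:
        raise ValueError(f"IoU between frames {a.frame!r} and {b.frame!r}")
    if a.area <= 0 or b.area <= 0:  # unreachable for valid boxes, kept for safety
        warnings.warn("IoU of a degenerate box is defined as 0", stacklevel=2)
        return 0.0
    inter = a.intersection_area(b)
    if inter <= 0:
        return 0.0
    return min(inter / (a.area + b.area - inter), 1.0)


def confidence_filter(
    dets: list[DetectionEvent],
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> list[DetectionEvent]:
    """Drop detections with confidence below ``threshold``, keeping order."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return [d for d in dets if d.confidence >= threshold]


def nms(
    dets: list[DetectionEvent], iou_threshold: float = DEFAULT_NMS_IOU
) -> list[DetectionEvent]:
    """Greedy class-wise non-maximum suppression on one frame's detections.

    Detections are visited in order of decreasing confidence (ties broken by
    input position, for determinism); each kept detection suppresses every
    not-yet-kept detection of the *same* class whose IoU with it is strictly
    greater than ``iou_threshold``.  Detections of different classes never
    suppress each other.  Returns survivors in the visiting order.
    """
    if not dets:
        return []
    frame_ids = {d.frame_id for d in dets}
    if len(frame_ids) > 1:
        raise ValueError(f"nms expects a single frame, got {sorted(frame_ids)}")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    suppressed = [False] * len(dets)
    keep: list[DetectionEvent] = []
    for i in order:
        if suppressed[i]:
            continue
        keep.append(dets[i])
        for j in order:
            if j == i or suppressed[j]:
                continue
            if dets[j].det_class != dets[i].det_class:
                continue
            if iou(dets[j].box, dets[i].box) > iou_threshold:
                suppressed[j] = True
    return keep
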