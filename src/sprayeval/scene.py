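"""Geometric world model: boxes, plants, camera frames, plots.

Conventions
-----------
Image frame: origin at the top-left pixel, x to the right (across track),
y downwards, 0-based, boxes half-open ``[x_min, x_min + width)``.  The image
y axis points *against* the driving direction, so the upper edge of an image
is the far edge of its ground footprint.

World frame: x along track (driving direction), y across track, metres,
origin at the footprint start of the first trigger of camera 0.  A frame's
``world_anchor`` is the world position of its image origin (pixel (0, 0)),
hence ``anchor.x = trigger_index * trigger_spacing + fov_along_track``.

The pixel-to-world conversion is a pure scale-and-translate: all pixels are
assumed to have a fixed metric size and a fixed location relative to the
robot.  No lens distortion or perspective model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "IMAGE",
    "WORLD",
    "SUGAR_BEET",
    "POTATO",
    "BACKGROUND",
    "PLANT_CLASSES",
    "BoundingBox",
    "CameraRig",
    "Frame",
    "Plot",
    "Plant",
    "image_to_world",
    "world_to_image",
    "frame_multiplicity",
    "frames_observing",
    "frame_footprint",
]

IMAGE = "image"
WORLD = "world"

SUGAR_BEET = "sugar_beet"
POTATO = "potato"
BACKGROUND = "background"
#: Valid plant classes.  ``background`` is an attribution outcome for
#: detections only; a ground-truth plant is always sugar_beet or potato.
PLANT_CLASSES = (SUGAR_BEET, POTATO, BACKGROUND)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, half-open, in image pixels or world metres."""

    x_min: float
    y_min: float
    width: float
    height: float
    frame: str = IMAGE  # IMAGE or WORLD

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"box must have positive extent, got {self.width} x {self.height}"
            )
        if self.frame not in (IMAGE, WORLD):
            raise ValueError(f"unknown reference frame {self.frame!r}")

    @property
    def x_max(self) -> float:
        return self.x_min + self.width

    @property
    def y_max(self) -> float:
        return self.y_min + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_min + self.width / 2.0, self.y_min + self.height / 2.0)

    def intersection_area(self, other: "BoundingBox") -> float:
        if self.frame != other.frame:
            raise ValueError(
                f"cannot intersect boxes in frames {self.frame!r} and {other.frame!r}"
            )
        w = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        h = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if w <= 0 or h <= 0:
            return 0.0
        return w * h

    def contains_point(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max

    def distance_to(self, other: "BoundingBox") -> float:
        """Minimum Euclidean gap between two boxes (0 if they touch/overlap)."""
        if self.frame != other.frame:
            raise ValueError("boxes in different reference frames")
        dx = max(self.x_min - other.x_max, other.x_min - self.x_max, 0.0)
        dy = max(self.y_min - other.y_max, other.y_min - self.y_max, 0.0)
        return math.hypot(dx, dy)

    def union_with(self, other: "BoundingBox") -> "BoundingBox":
        """Smallest box enclosing both boxes."""
        if self.frame != other.frame:
            raise ValueError("boxes in different reference frames")
        x0 = min(self.x_min, other.x_min)
        y0 = min(self.y_min, other.y_min)
        return BoundingBox(
            x0,
            y0,
            max(self.x_max, other.x_max) - x0,
            max(self.y_max, other.y_max) - y0,
            self.frame,
        )


@dataclass(frozen=True)
class CameraRig:
    """The multi-camera acquisition geometry.

    Defaults match a 4-camera rig with a per-camera footprint of 0.53 m along
    and 0.70 m across the driving direction, triggered every 0.25 m, so one
    world point is seen up to three times.  Across-track fields of adjacent
    cameras do not overlap.
    """

    fov_along_track: float = 0.53
    fov_across_track: float = 0.70
    trigger_spacing: float = 0.25
    image_width_px: int = 2048
    image_height_px: int = 1536
    n_cameras: int = 4
    camera_offsets_across_track: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.trigger_spacing <= 0:
            raise ValueError("trigger_spacing must be positive")
        if self.fov_along_track <= 0 or self.fov_across_track <= 0:
            raise ValueError("fields of view must be positive")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not self.camera_offsets_across_track:
            object.__setattr__(
                self,
                "camera_offsets_across_track",
                tuple(i * self.fov_across_track for i in range(self.n_cameras)),
            )
        if len(self.camera_offsets_across_track) != self.n_cameras:
            raise ValueError("need one across-track offset per camera")
        offs = sorted(self.camera_offsets_across_track)
        for a, b in zip(offs, offs[1:]):
            if b - a < self.fov_across_track - 1e-12:
                raise ValueError("adjacent camera fields must not overlap across track")

    @property
    def scale_along(self) -> float:
        """Metres per pixel on the image y axis (along track)."""
        return self.fov_along_track / self.image_height_px

    @property
    def scale_across(self) -> float:
        """Metres per pixel on the image x axis (across track)."""
        return self.fov_across_track / self.image_width_px


@dataclass(frozen=True)
class Frame:
    """One triggered image of one camera, anchored in the world."""

    frame_id: str
    camera_index: int
    trigger_index: int
    world_anchor: tuple[float, float]

    @staticmethod
    def build(camera_index: int, trigger_index: int, rig: CameraRig,
              frame_id: str | None = None) -> "Frame":
        """Construct the frame at a trigger, deriving its world anchor.

        The image origin (top-left pixel) is the far corner of the footprint,
        so the anchor sits at ``trigger * spacing + fov_along`` along track.
        """
        ax = trigger_index * rig.trigger_spacing + rig.fov_along_track
        ay = rig.camera_offsets_across_track[camera_index]
        if frame_id is None:
            frame_id = f"c{camera_index}_t{trigger_index}"
        return Frame(frame_id, camera_index, trigger_index, (ax, ay))


@dataclass(frozen=True)
class Plot:
    """One field trial plot: four sugar-beet rows, 2 m by 12.5 m by default."""

    plot_id: int
    soil_type: str = "sandy"
    contains_barley: bool = False
    length_m: float = 12.5
    width_m: float = 2.0
    n_rows: int = 4
    inter_row_m: float = 0.5
    intra_row_m: float = 0.19

    def __post_init__(self) -> None:
        if self.length_m <= 0 or self.width_m <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.n_rows < 1:
            raise ValueError("plot needs at least one row")
        if self.n_rows * self.inter_row_m > self.width_m + self.inter_row_m:
            raise ValueError("rows do not fit in the plot width")

    def row_positions(self, across_offset: float = 0.0) -> list[float]:
        """Across-track centres of the crop rows, rows centred in the plot."""
        span = (self.n_rows - 1) * self.inter_row_m
        start = across_offset + (self.width_m - span) / 2.0
        return [start + i * self.inter_row_m for i in range(self.n_rows)]


@dataclass
class Plant:
    """A ground-truth organism with its world box and per-frame observations."""

    plant_id: str
    plant_class: str
    world_box: BoundingBox
    observations: list[tuple[str, BoundingBox]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.plant_class not in (SUGAR_BEET, POTATO):
            raise ValueError(
                f"ground-truth plant class must be sugar_beet or potato, "
                f"got {self.plant_class!r}"
            )
        if self.world_box.frame != WORLD:
            raise ValueError("plant world_box must be in the world frame")


def image_to_world(box: BoundingBox, frame: Frame, rig: CameraRig) -> BoundingBox:
    """Project an image-frame box to world metres.

    Linear scale-and-translate under the fixed-pixel-size assumption.  The
    image y axis (downwards) maps to decreasing world x (along track); the
    image x axis maps to increasing world y (across track).
    """
    if box.frame != IMAGE:
        raise ValueError("expected an image-frame box")
    tol = 1e-6  # px; absorbs float round-trip error at the image border
    if (box.x_min < -tol or box.y_min < -tol
            or box.x_max > rig.image_width_px + tol
            or box.y_max > rig.image_height_px + tol):
        raise ValueError(
            f"box {box} lies outside the {rig.image_width_px}x"
            f"{rig.image_height_px} image bounds"
        )
    ax, ay = frame.world_anchor
    return BoundingBox(
        x_min=ax - box.y_max * rig.scale_along,
        y_min=ay + box.x_min * rig.scale_across,
        width=box.height * rig.scale_along,
        height=box.width * rig.scale_across,
        frame=WORLD,
    )


def world_to_image(box: BoundingBox, frame: Frame, rig: CameraRig) -> BoundingBox:
    """Inverse of :func:`image_to_world`; the box must fall inside the frame."""
    if box.frame != WORLD:
        raise ValueError("expected a world-frame box")
    ax, ay = frame.world_anchor
    img = BoundingBox(
        x_min=(box.y_min - ay) / rig.scale_across,
        y_min=(ax - box.x_max) / rig.scale_along,
        width=box.height / rig.scale_across,
        height=box.width / rig.scale_along,
        frame=IMAGE,
    )
    if (img.x_min < -1e-9 or img.y_min < -1e-9
            or img.x_max > rig.image_width_px + 1e-9
            or img.y_max > rig.image_height_px + 1e-9):
        raise ValueError(f"world box {box} does not fall inside frame {frame.frame_id}")
    return img


def frame_footprint(frame: Frame, rig: CameraRig) -> BoundingBox:
    """World-frame ground footprint of a frame."""
    ax, ay = frame.world_anchor
    return BoundingBox(
        ax - rig.fov_along_track, ay, rig.fov_along_track, rig.fov_across_track, WORLD
    )


def frame_multiplicity(rig: CameraRig) -> int:
    """Maximum number of one camera's frames that can observe a single point.

    With footprints of length F triggered every s, a point can fall into at
    most ``floor(F / s) + 1`` consecutive footprints (3 for F=0.53, s=0.25).
    """
    return int(math.floor(rig.fov_along_track / rig.trigger_spacing)) + 1


def frames_observing(
    point: tuple[float, float], frames: Iterable[Frame], rig: CameraRig
) -> list[str]:
    """Ids of the frames whose footprint contains the world point.

    Footprints are half-open consistently with the image-box convention:
    pixel y in [0, H) maps to world x in (anchor_x - fov, anchor_x], so a
    point exactly at a frame's anchor is observed by that frame.
    """
    x, y = point
    out = []
    for f in frames:
        ax, ay = f.world_anchor
        if (ax - rig.fov_along_track < x <= ax
                and ay <= y < ay + rig.fov_across_track):
            out.append(f.frame_id)
    return out
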