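"""Nozzle-section spray planning and field-level outcome scoring.

The boom carries individually switchable nozzles (29 by default, 9.5 cm
apart, each wetting a ~10 cm strip), so the sprayed area is a union of
rectangles: a nozzle's fixed across-track section times an along-track
interval taken from the detection's own bounding box.  Any nozzle whose
section overlaps a potato detection, even partly, is activated — duplicated
detections from overlapping images simply re-activate the same nozzles.

Field-level scoring replays the manual field count: a plant is "hit" when
its (optionally dilated) world box intersects the sprayed area, and a hit
sugar beet is attributed to the coarse spray resolution when it lies within
``near_radius_m`` of a hit potato.  Plot percentages are pooled as the
unweighted mean of per-plot percentages (a count-weighted pooled value is
reported alongside, clearly labelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .scene import BoundingBox, Plant, POTATO, SUGAR_BEET, WORLD

__all__ = [
    "NozzleArray",
    "SprayMap",
    "FieldReport",
    "plan_spray",
    "score_field",
    "throttle_detections",
    "percent_half_up",
]


@dataclass(frozen=True)
class NozzleArray:
    """Geometry and switching speed of the spray boom."""

    n_nozzles: int = 29
    spacing_m: float = 0.095
    section_width_m: float = 0.10
    switch_time_s: float = 0.010
    boom_offset_across_track_m: float = 0.05

    def __post_init__(self) -> None:
        if self.n_nozzles < 1:
            raise ValueError("need at least one nozzle")
        if self.spacing_m <= 0 or self.section_width_m <= 0:
            raise ValueError("nozzle spacing and section width must be positive")

    def section_interval(self, i: int) -> tuple[float, float]:
        """Across-track [start, end) of nozzle ``i``'s wetted strip.

        Sections are slightly wider than the nozzle pitch (0.10 m vs
        0.095 m), so adjacent strips overlap a little — modelled literally.
        """
        center = self.boom_offset_across_track_m + i * self.spacing_m
        half = self.section_width_m / 2.0
        return (center - half, center + half)


@dataclass
class SprayMap:
    """Per-nozzle along-track activation intervals, overlaps merged."""

    activations: list[tuple[int, tuple[float, float]]] = field(default_factory=list)

    def covers_point(self, x: float, y: float, nozzles: NozzleArray) -> bool:
        for i, (x0, x1) in self.activations:
            s0, s1 = nozzles.section_interval(i)
            if x0 <= x < x1 and s0 <= y < s1:
                return True
        return False

    def intersects_box(self, box: BoundingBox, nozzles: NozzleArray) -> bool:
        if box.frame != WORLD:
            raise ValueError("spray map lives in the world frame")
        for i, (x0, x1) in self.activations:
            s0, s1 = nozzles.section_interval(i)
            if (min(x1, box.x_max) - max(x0, box.x_min) > 0
                    and min(s1, box.y_max) - max(s0, box.y_min) > 0):
                return True
        return False


def _merge_intervals(ivals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for x0, x1 in sorted(ivals):
        if out and x0 <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], x1))
        else:
            out.append((x0, x1))
    return out


def plan_spray(
    potato_det_boxes: list[BoundingBox],
    nozzles: NozzleArray,
    speed_mps: float = 0.0,
    det_classes: list[str] | None = None,
) -> SprayMap:
    """Turn world-projected potato detections into nozzle activations.

    Every nozzle whose section intersects a detection's across-track extent
    activates over the detection's along-track extent, expanded where needed
    to the controller quantum ``speed_mps * switch_time_s`` (0 when no travel
    speed is configured, i.e. instantaneous switching).
    """
    if det_classes is not None:
        for c in det_classes:
            if c != POTATO:
                raise ValueError(f"only potato detections trigger spraying, got {c!r}")
    quantum = speed_mps * nozzles.switch_time_s
    per_nozzle: dict[int, list[tuple[float, float]]] = {}
    for box in potato_det_boxes:
        if box.frame != WORLD:
            raise ValueError("detections must be world-projected before planning")
        x0, x1 = box.x_min, box.x_max
        if x1 - x0 < quantum:  # shortest realizable squirt
            pad = (quantum - (x1 - x0)) / 2.0
            x0, x1 = x0 - pad, x1 + pad
        for i in range(nozzles.n_nozzles):
            s0, s1 = nozzles.section_interval(i)
            if min(s1, box.y_max) - max(s0, box.y_min) > 0:
                per_nozzle.setdefault(i, []).append((x0, x1))
    activations = [
        (i, iv) for i in sorted(per_nozzle) for iv in _merge_intervals(per_nozzle[i])
    ]
    return SprayMap(activations=activations)


def throttle_detections(
    dets_with_time: list[tuple[float, object]], max_per_second: float = 5.0
) -> list[object]:
    """Optional controller-rate limit: drop the oldest queued detections.

    The boom controller accepts at most ``max_per_second`` detections; with
    timestamps given, detections arriving faster than the budget displace
    the oldest ones still queued.  Off by default in the pipeline (no travel
    speed is assumed), provided for completeness.
    """
    if max_per_second <= 0:
        raise ValueError("max_per_second must be positive")
    min_gap = 1.0 / max_per_second
    kept: list[tuple[float, object]] = []
    for t, d in sorted(dets_with_time, key=lambda td: td[0]):
        if kept and t - kept[-1][0] < min_gap - 1e-12:
            kept[-1] = (t, d)  # newest displaces the oldest queued
        else:
            kept.append((t, d))
    return [d for _, d in kept]


def percent_half_up(x: float) -> int:
    """Round a percentage to the printed integer style (half away from zero)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class PlotFieldCounts:
    potatoes_total: int = 0
    potatoes_sprayed: int = 0
    beets_total: int = 0
    beets_hit: int = 0
    beets_hit_near_potato: int = 0

    @property
    def potatoes_sprayed_pct(self) -> float | None:
        if self.potatoes_total == 0:
            return None
        return 100.0 * self.potatoes_sprayed / self.potatoes_total

    @property
    def beets_hit_pct(self) -> float | None:
        if self.beets_total == 0:
            return None
        return 100.0 * self.beets_hit / self.beets_total

    @property
    def beets_hit_near_potato_pct(self) -> float | None:
        """Share of the *hit* beets attributable to coarse spray resolution."""
        if self.beets_hit == 0:
            return None
        return 100.0 * self.beets_hit_near_potato / self.beets_hit

    def add(self, other: "PlotFieldCounts") -> None:
        self.potatoes_total += other.potatoes_total
        self.potatoes_sprayed += other.potatoes_sprayed
        self.beets_total += other.beets_total
        self.beets_hit += other.beets_hit
        self.beets_hit_near_potato += other.beets_hit_near_potato


@dataclass
class FieldReport:
    per_plot: dict[int, PlotFieldCounts]
    pooled_weighted: PlotFieldCounts
    params: dict

    def _plot_mean(self, attr: str) -> float | None:
        vals = [getattr(c, attr) for c in self.per_plot.values()]
        vals = [v for v in vals if v is not None]
        if not vals:
            return None
        return sum(vals) / len(vals)

    @property
    def potatoes_sprayed_pct_mean(self) -> float | None:
        return self._plot_mean("potatoes_sprayed_pct")

    @property
    def beets_hit_pct_mean(self) -> float | None:
        return self._plot_mean("beets_hit_pct")

    @property
    def beets_hit_near_potato_pct_mean(self) -> float | None:
        return self._plot_mean("beets_hit_near_potato_pct")

    def as_dict(self) -> dict:
        def row(c: PlotFieldCounts) -> dict:
            def p(v):
                return "undefined" if v is None else v

            return {
                "potatoes_total": c.potatoes_total,
                "potatoes_sprayed": c.potatoes_sprayed,
                "potatoes_sprayed_pct": p(c.potatoes_sprayed_pct),
                "beets_total": c.beets_total,
                "beets_hit": c.beets_hit,
                "beets_hit_pct": p(c.beets_hit_pct),
                "beets_hit_near_potato": c.beets_hit_near_potato,
                "beets_hit_near_potato_pct": p(c.beets_hit_near_potato_pct),
            }

        def p(v):
            return "undefined" if v is None else v

        return {
            "level": "field",
            "params": self.params,
            "per_plot": {str(k): row(c) for k, c in sorted(self.per_plot.items())},
            "pooled_plot_mean": {
                "potatoes_sprayed_pct": p(self.potatoes_sprayed_pct_mean),
                "beets_hit_pct": p(self.beets_hit_pct_mean),
                "beets_hit_near_potato_pct": p(self.beets_hit_near_potato_pct_mean),
            },
            "pooled_count_weighted": row(self.pooled_weighted),
        }


def score_field(
    spray: SprayMap,
    plants: list[Plant],
    nozzles: NozzleArray,
    hit_margin_m: float = 0.0,
    near_radius_m: float = 0.10,
    plot_of_plant: dict[str, int] | None = None,
) -> FieldReport:
    """Count sprayed potatoes and hit beets, attributing near-potato hits.

    A plant is hit when its world box, dilated by ``hit_margin_m``, overlaps
    any activation rectangle.  A hit beet counts as "close to a potato" when
    its box lies within ``near_radius_m`` (default: one section width) of a
    hit potato's box.
    """

    def dilated(b: BoundingBox) -> BoundingBox:
        if hit_margin_m <= 0:
            return b
        return BoundingBox(
            b.x_min - hit_margin_m, b.y_min - hit_margin_m,
            b.width + 2 * hit_margin_m, b.height + 2 * hit_margin_m, b.frame,
        )

    hit: dict[str, bool] = {
        p.plant_id: spray.intersects_box(dilated(p.world_box), nozzles)
        for p in plants
    }
    hit_potatoes = [p for p in plants if p.plant_class == POTATO and hit[p.plant_id]]

    per_plot: dict[int, PlotFieldCounts] = {}
    pooled = PlotFieldCounts()
    for p in plants:
        plot = plot_of_plant.get(p.plant_id, -1) if plot_of_plant else -1
        c = per_plot.setdefault(plot, PlotFieldCounts())
        if p.plant_class == POTATO:
            c.potatoes_total += 1
            if hit[p.plant_id]:
                c.potatoes_sprayed += 1
        elif p.plant_class == SUGAR_BEET:
            c.beets_total += 1
            if hit[p.plant_id]:
                c.beets_hit += 1
                near = any(
                    p.world_box.distance_to(q.world_box) <= near_radius_m
                    for q in hit_potatoes
                )
                if near:
                    c.beets_hit_near_potato += 1
    for c in per_plot.values():
        pooled.add(c)
    params = {"hit_margin_m": hit_margin_m, "near_radius_m": near_radius_m}
    return FieldReport(per_plot=per_plot, pooled_weighted=pooled, params=params)
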