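"""Reference experiments: headline pipeline summaries and recall recovery.

These are the computations a user reproduces to sanity-check the stack:
the three-tier summary of the default synthetic trial, the closed-form
multi-view recall recovery (a plant seen v times by a detector missing each
view independently with probability p is found with probability 1 - p^v),
and the printed-table arithmetic shipped with the package.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources

import pandas as pd

from .application_eval import cluster_plants, evaluate_application
from .config import RunConfig
from .pipeline import postprocess_detections, run_in_memory
from .scene import POTATO, Plot, frame_multiplicity
from .sprayer import percent_half_up
from .synthetic import (
    PERFECT_DETECTOR,
    ScenarioConfig,
    generate_detections,
    generate_scene,
)

__all__ = [
    "packaged_table",
    "training_data_totals",
    "near_potato_reference_average",
    "multi_view_recall_experiment",
    "default_trial_summary",
]


def packaged_table(name: str) -> pd.DataFrame:
    """Load one of the reference tables shipped with the package."""
    path = resources.files("sprayeval.data") / name
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def training_data_totals() -> tuple[int, int, int]:
    """(images, beet, potato) annotation totals of the training manifest."""
    from .formats import summarize_manifest

    return summarize_manifest(packaged_table("training_manifest.csv"))


def near_potato_reference_average() -> int:
    """Mean of the per-plot near-potato percentages, printed-style rounded."""
    pcts = packaged_table("field_near_potato_pct.csv")[
        "pct_beets_hit_close_to_potato"
    ]
    return percent_half_up(float(pcts.mean()))


def multi_view_recall_experiment(
    n_scenes: int = 100,
    base_seed: int = 0,
    miss_prob: float = 0.4,
    views: int = 3,
) -> dict:
    """Plant-level recall among plants seen exactly ``views`` times.

    Runs single-plot scenes with a detector that misses every observation
    independently with probability ``miss_prob`` (no other error modes) and
    pools the plant-level verdicts of the potatoes the rig observed exactly
    ``views`` times.  The closed-form expectation is ``1 - miss_prob**views``;
    the returned dict carries the measured recall, the expectation and the
    binomial standard error at the pooled sample size.
    """
    plots = (Plot(plot_id=1, soil_type="sandy"),)
    model = dataclasses.replace(
        PERFECT_DETECTOR,
        miss_prob_base=miss_prob, miss_prob_top_edge=miss_prob,
    )
    config = RunConfig()
    hits = 0
    total = 0
    for k in range(n_scenes):
        seed = (base_seed * 100_003 + k) % (2**31 - 1)
        cfg = ScenarioConfig(plots=plots, seed=seed)
        scene = generate_scene(cfg)
        raw = generate_detections(scene, model, seed)
        dets = postprocess_detections(raw, config)
        plants = cluster_plants(scene.gts_by_frame, scene.frames, scene.rig)
        report = evaluate_application(plants, dets, scene.frames, scene.rig)
        verdict_of = {v.plant_id: v.verdict for v in report.verdicts}
        for p in plants:
            if p.plant_class != POTATO or len(p.observations) != views:
                continue
            total += 1
            if verdict_of[p.plant_id] == "TP":
                hits += 1
    expected = 1.0 - miss_prob**views
    recall = hits / total if total else float("nan")
    se = math.sqrt(expected * (1.0 - expected) / total) if total else float("nan")
    return {
        "recall": recall,
        "expected": expected,
        "binomial_se": se,
        "n_plants": total,
        "n_scenes": n_scenes,
        "miss_prob": miss_prob,
        "views": views,
    }


def default_trial_summary(seed: int) -> dict:
    """All three evaluation tiers on the default eight-plot synthetic trial."""
    res = run_in_memory(RunConfig(seed=seed))
    img = res.image_report.pooled[POTATO]
    app = res.application_report.pooled
    fld = res.field_report
    n_beets = sum(1 for p in res.plants if p.plant_class != POTATO)
    comp = app.composition()
    return {
        "image": {
            "precision": img.precision, "recall": img.recall,
            "tp": img.tp, "fp": img.fp, "fn": img.fn,
        },
        "application": {
            "potato_recall": app.potato_recall,
            "potato_tp": app.potato_tp, "potato_fn": app.potato_fn,
            "beet_fp": app.beet_fp, "beet_fp_pct": 100.0 * app.beet_fp / n_beets,
            "background_fp": app.background_fp,
            "background_share": comp["background"] if comp else None,
        },
        "field": {
            "potatoes_sprayed_pct": fld.potatoes_sprayed_pct_mean,
            "beets_hit_pct": fld.beets_hit_pct_mean,
            "beets_hit_near_potato_pct": fld.beets_hit_near_potato_pct_mean,
        },
        "n_potatoes": app.potato_tp + app.potato_fn,
        "n_beets": n_beets,
        "frame_multiplicity": frame_multiplicity(res.scene.rig),
    }
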