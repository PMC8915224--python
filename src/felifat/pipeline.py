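"""End-to-end orchestration: phantom cohort -> CT composition -> FFR ->
cutoffs -> FFR classification -> diagnostics -> cohort statistics.

Every random step derives from the single seed in RunConfig, so a run is
bitwise reproducible.  All rounding happens at the report layer; internal
values keep full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import pandas as pd

from ._util import round_half_away
from . import cohort_stats, cutoffs as co
from .ct import UndefinedFatPeakError, analyze_volume
from .phantom import generate_cohort

logger = logging.getLogger("felifat")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_cats: int = 40
    fat_fraction_range: tuple[float, float] = (0.10, 0.60)
    cutoff_mode: str = "derived"  # "derived" | "fixed_published"
    smooth_window: int = 11
    prominence_fraction: float = 0.005
    min_separation: int = 30
    report_precision: int = 2

    def __post_init__(self) -> None:
        if self.cutoff_mode not in ("derived", "fixed_published"):
            raise ValueError(f"unknown cutoff_mode {self.cutoff_mode!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis on a generated cohort; returns the report.

    Cats whose soft-tissue histogram lacks a defined fat peak are
    excluded from composition (and from everything downstream that needs
    CT metrics) and listed in the report with the reason.
    """
    nd = config.report_precision
    triples, records = generate_cohort(
        n_cats=config.n_cats,
        fat_fraction_range=config.fat_fraction_range,
        seed=config.seed,
    )

    compositions = []
    exclusions = []
    for volume, masks, truth in triples:
        try:
            comp = analyze_volume(
                volume,
                masks,
                smooth_window=config.smooth_window,
                prominence_fraction=config.prominence_fraction,
                min_separation=config.min_separation,
            )
        except UndefinedFatPeakError as exc:
            logger.warning("excluding %s: %s", volume.cat_id, exc)
            exclusions.append(
                {"cat_id": volume.cat_id, "reason": str(exc)}
            )
            continue
        compositions.append(
            {
                "cat_id": comp.cat_id,
                "fat_voxels": comp.fat_voxels,
                "lean_voxels": comp.lean_voxels,
                "bone_voxels": comp.bone_voxels,
                "pbf": comp.pbf,
                "bfv": comp.bfv,
                "tbbv": comp.tbbv,
                "nbfv": comp.nbfv,
                "true_bfv": truth.true_bfv,
            }
        )
    comp_columns = [
        "cat_id",
        "fat_voxels",
        "lean_voxels",
        "bone_voxels",
        "pbf",
        "bfv",
        "tbbv",
        "nbfv",
        "true_bfv",
    ]
    comp_df = pd.DataFrame(compositions, columns=comp_columns)

    records = records.copy()
    records["ffr"] = records["ffpw"] / records["fl"]
    table = records.merge(comp_df, on="cat_id", how="left")

    if config.cutoff_mode == "fixed_published":
        cutoff_set = co.FIXED_PUBLISHED_CUTOFFS
    else:
        with_ct = table.dropna(subset=["nbfv"])
        nbfv_by_fc = {
            fc: with_ct.loc[with_ct["visual_fc"] == fc, "nbfv"].tolist()
            for fc in ("normal", "overweight", "obese")
        }
        # below-scale FFPW gives FFR 0, undefined under the ln transform
        ffr_fit = cohort_stats.correlate(
            with_ct[with_ct["ffr"] > 0], "nbfv", "ffr", transform_policy="ln"
        )
        pbf_fit = cohort_stats.correlate(
            with_ct, "nbfv", "pbf", transform_policy="none"
        )
        cutoff_set = co.derive_cutoff_set(nbfv_by_fc, ffr_fit, pbf_fit)

    table["ffr_class"] = [
        co.classify_by_ffr(f, cutoff_set) for f in table["ffr"]
    ]
    diagnostics = {}
    for cond in ("obesity", "overweight"):
        counts = co.confusion_table(table, cond)
        if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
            # a margin is empty (e.g. no visually obese cat generated)
            diagnostics[cond] = {
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "tn": counts.tn,
                "note": "empty disease margin; sensitivity/specificity undefined",
            }
        else:
            diagnostics[cond] = co.performance_report(co.sens_spec_with_ci(counts))

    with_ct = table.dropna(subset=["nbfv"])
    stats_report = {}
    for label, xcol, ycol, policy in (
        ("ffpw_vs_bfv", "bfv", "ffpw", "none"),
        ("ffr_vs_nbfv", "nbfv", "ffr", "ln"),
        ("pbf_vs_nbfv", "nbfv", "pbf", "none"),
    ):
        sub = with_ct[with_ct["ffr"] > 0] if policy == "ln" else with_ct
        if len(sub) < 3:
            stats_report[label] = None
            continue
        fit = cohort_stats.correlate(sub, xcol, ycol, transform_policy=policy)
        stats_report[label] = {
            "intercept": round_half_away(fit.intercept, 3),
            "slope": round_half_away(fit.slope, 3),
            "r": round_half_away(fit.r, 3),
            "r2": round_half_away(fit.r2, 3),
            "transform": fit.transform,
        }

    report = {
        "config": {
            "seed": config.seed,
            "n_cats": config.n_cats,
            "fat_fraction_range": list(config.fat_fraction_range),
            "cutoff_mode": config.cutoff_mode,
        },
        "compositions": [
            {
                "cat_id": r["cat_id"],
                "pbf": round_half_away(r["pbf"], nd),
                "bfv": round_half_away(r["bfv"], nd),
                "tbbv": round_half_away(r["tbbv"], nd),
                "nbfv": round_half_away(r["nbfv"], nd),
            }
            for r in compositions
        ],
        "exclusions": exclusions,
        "ffr": {
            row["cat_id"]: round_half_away(row["ffr"], 1)
            for _, row in table.iterrows()
        },
        "classifications": dict(zip(table["cat_id"], table["ffr_class"])),
        "cutoffs": {
            "nbfv_overweight": round_half_away(cutoff_set.nbfv_overweight, 3),
            "nbfv_obese": round_half_away(cutoff_set.nbfv_obese, 3),
            "ffr_overweight": round_half_away(cutoff_set.ffr_overweight, 1),
            "ffr_obese": round_half_away(cutoff_set.ffr_obese, 1),
            "pbf_overweight": round_half_away(cutoff_set.pbf_overweight, 1),
            "pbf_obese": round_half_away(cutoff_set.pbf_obese, 1),
        },
        "diagnostics": diagnostics,
        "stats": stats_report,
    }
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
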