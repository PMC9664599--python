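"""End-to-end workflow: simulate → cost → standardize → compare → scale.

Thin orchestration over the library modules; every CLI subcommand and
analysis driver calls into these functions so results are identical whichever
entry point is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as hio
from .costing import CostingResult, compute_centre_costs
from .simulate import GeneratorConfig, SyntheticDataset, default_study_config, generate_dataset
from .standardize import StandardizationResult, standardize_dataset
from .stats import compare_groups, pairwise_compare, scale_correlation
from .types import GroupComparison, Metric, PipelineConfig, ScaleCorrelation

log = logging.getLogger("hospicost")

#: (centre_kind, metric) pairs reported in the group comparisons.
COMPARISON_OUTCOMES = (
    ("OP", Metric.PER_VISIT.value),
    ("IP", Metric.PER_ADMISSION.value),
    ("IP", Metric.PER_BED_DAY.value),
    ("ICU", Metric.PER_ADMISSION.value),
    ("ICU", Metric.PER_BED_DAY.value),
    ("OT", Metric.PER_PROCEDURE.value),
)

SCALE_VARIABLES = ("admissions", "beds", "bed_occupancy", "opd_visits")


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    costing: CostingResult
    standardized: StandardizationResult
    comparisons: pd.DataFrame
    scale: list[ScaleCorrelation] = field(default_factory=list)
    comparison_objects: list[GroupComparison] = field(default_factory=list)


def attach_groups(table: pd.DataFrame, facilities: pd.DataFrame) -> pd.DataFrame:
    return table.merge(
        facilities[["facility_id", "provider_type", "city_tier"]], on="facility_id", how="left"
    )


def comparison_frame(
    standardized: pd.DataFrame,
    facilities: pd.DataFrame,
    groupings: tuple[str, ...] = ("provider_type", "city_tier"),
    cost_columns: tuple[str, ...] = ("unadjusted", "adjusted_80", "adjusted_100"),
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Run every (centre, metric, grouping, adjustment) comparison that has at
    least two nonempty groups; returns a tidy frame plus the full objects."""
    merged = attach_groups(standardized, facilities)
    rows, objects = [], []
    for centre, metric in COMPARISON_OUTCOMES:
        sub = merged[(merged["centre_kind"] == centre) & (merged["metric"] == metric)]
        if sub.empty:
            continue
        for grouping in groupings:
            for col in cost_columns:
                if sub.groupby(grouping)[col].count().gt(0).sum() < 2:
                    continue
                comp = compare_groups(sub, grouping, col)
                objects.append(comp)
                for g in comp.groups:
                    rows.append(
                        {
                            "centre_kind": centre,
                            "metric": metric,
                            "grouping": grouping,
                            "cost_basis": col,
                            "group": g.group,
                            "n": g.n,
                            "median": g.median,
                            "q1": g.q1,
                            "q3": g.q3,
                            "H": comp.H,
                            "p": comp.p,
                            "eta2": comp.eta2,
                            "effect_label": comp.effect_label,
                        }
                    )
    return pd.DataFrame(rows), objects


def scale_analysis(
    standardized: pd.DataFrame,
    utilization: pd.DataFrame,
    facilities: pd.DataFrame,
    span: float = 2.0 / 3.0,
    provider_type: Optional[str] = "district",
) -> list[ScaleCorrelation]:
    """Cost–scale correlations with LOWESS curves.

    Follows the comparability restriction to a single provider type (default
    district) and to the inpatient/outpatient centres: per-bed-day and
    per-admission IP costs against admissions, beds and bed occupancy, and
    per-visit OP cost against visit volume.
    """
    util = utilization.copy()
    util["bed_occupancy"] = np.where(
        util["beds"] > 0,
        util["admissions"] * util["alos_days"] / (util["beds"] * 365.0),
        np.nan,
    )
    merged = attach_groups(standardized, facilities).merge(
        util[["facility_id", "specialty", "admissions", "beds", "bed_occupancy", "opd_visits"]],
        on=["facility_id", "specialty"],
        how="left",
    )
    if provider_type is not None:
        merged = merged[merged["provider_type"] == provider_type]

    out: list[ScaleCorrelation] = []
    plans = [
        ("IP", Metric.PER_BED_DAY.value, "admissions"),
        ("IP", Metric.PER_BED_DAY.value, "beds"),
        ("IP", Metric.PER_BED_DAY.value, "bed_occupancy"),
        ("IP", Metric.PER_ADMISSION.value, "admissions"),
        ("IP", Metric.PER_ADMISSION.value, "beds"),
        ("IP", Metric.PER_ADMISSION.value, "bed_occupancy"),
        ("OP", Metric.PER_VISIT.value, "opd_visits"),
    ]
    for centre, metric, xvar in plans:
        sub = merged[(merged["centre_kind"] == centre) & (merged["metric"] == metric)].dropna(
            subset=[xvar, "unadjusted"]
        )
        if len(sub) < 10:
            continue
        out.append(
            scale_correlation(
                sub[xvar].to_numpy(),
                sub["unadjusted"].to_numpy(),
                x_name=xvar,
                y_name=f"{centre}_{metric}",
                span=span,
            )
        )
    return out


def run_pipeline(
    gen_config: Optional[GeneratorConfig] = None,
    pipe_config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Full workflow on a (generated) dataset; optionally writes all tables."""
    gen_config = gen_config if gen_config is not None else default_study_config()
    pipe = pipe_config if pipe_config is not None else PipelineConfig(seed=gen_config.seed)
    pipe.validate()

    dataset = generate_dataset(gen_config)
    log.info(
        "generated dataset: config=%s seed=%d facilities=%d line_items=%d utilization=%d",
        hio.config_hash(gen_config),
        gen_config.seed,
        len(dataset.facilities),
        len(dataset.line_items),
        len(dataset.utilization),
    )

    costing = compute_centre_costs(
        dataset.line_items, dataset.utilization, discount_rate=pipe.discount_rate
    )
    for fid, spec, centre, reason in costing.dropped:
        log.warning("dropped centre %s/%s/%s: %s", fid, spec, centre, reason)

    standardized = standardize_dataset(
        costing.costs,
        dataset.utilization,
        targets=pipe.targets,
        days_per_year=pipe.days_per_year,
        bor_stability_floor=pipe.bor_stability_floor,
    )
    for fid, spec, centre, reason in standardized.skipped:
        log.warning("skipped standardization %s/%s/%s: %s", fid, spec, centre, reason)

    comparisons, comp_objects = comparison_frame(standardized.table, dataset.facilities)
    scale = scale_analysis(
        standardized.table, dataset.utilization, dataset.facilities, span=pipe.smoothing_span
    )

    result = PipelineResult(
        dataset=dataset,
        costing=costing,
        standardized=standardized,
        comparisons=comparisons,
        scale=scale,
        comparison_objects=comp_objects,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_tables(dataset, out)
        costing.costs.to_csv(out / "unit_costs.csv", index=False)
        standardized.table.to_csv(out / "standardized.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        curve_rows = [
            {"y": sc.y, "x": sc.x, "r": sc.r, "p": sc.p, "n": sc.n, "curve_x": cx, "curve_y": cy}
            for sc in scale
            for cx, cy in zip(sc.curve_x, sc.curve_y)
        ]
        pd.DataFrame(curve_rows).to_csv(out / "scale_curves.csv", index=False)
    return result
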