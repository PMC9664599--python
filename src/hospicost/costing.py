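"""Cost-centre costing: annualization, fixed/variable classification,
top-down apportionment of shared inputs, and unit costs per metric.

Top-down costing attributes annual resource totals (salaries, annualized
capital, supplies, overheads) to the OP/IP/ICU cost centres of each specialty
and divides by annual service output; operating-theatre costs mix a top-down
fixed share with bottom-up per-procedure resource use. Every line item maps
to exactly one of the fixed/variable classes, so each centre's total
decomposes exactly as F + V — the decomposition the occupancy standardization
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import AllocationError, DomainError
from .types import (
    Category,
    CentreKind,
    CostClass,
    FIXED_CATEGORIES,
    Metric,
    VARIABLE_CATEGORIES,
)


def annualize_capital(purchase_price: float, useful_life: float, discount_rate: float) -> float:
    """Equivalent annual cost of a capital purchase.

    Annuity formula price * r / (1 - (1+r)^-life); the zero-rate limit is
    straight-line depreciation price / life.
    """
    if useful_life <= 0:
        raise DomainError(f"useful_life must be > 0, got {useful_life}")
    if purchase_price < 0:
        raise DomainError(f"purchase_price must be >= 0, got {purchase_price}")
    if discount_rate < 0:
        raise DomainError(f"discount_rate must be >= 0, got {discount_rate}")
    if discount_rate == 0:
        return purchase_price / useful_life
    # 1 - (1+r)^-n via expm1/log1p: stable for tiny rates (limit -> straight line)
    denom = -np.expm1(-useful_life * np.log1p(discount_rate))
    return purchase_price * discount_rate / denom


def classify_cost(category: Category | str) -> CostClass:
    """Fixed: salaries and annualized capital (space, equipment, furniture).
    Variable: everything that moves with output — including equipment
    maintenance, even though the equipment capital itself is fixed."""
    cat = Category(category)
    if cat in FIXED_CATEGORIES:
        return CostClass.FIXED
    if cat in VARIABLE_CATEGORIES:
        return CostClass.VARIABLE
    raise DomainError(f"unknown category: {category}")  # pragma: no cover


def apportion_shared(
    item_totals: Iterable[float], weights: Mapping[str, float]
) -> dict[str, float]:
    """Distribute shared annual costs across centres proportionally to weights.

    Conservation holds by construction: for each item the distributed amounts
    sum to the item total (floating-point error far below one paisa).
    """
    w = dict(weights)
    if any(v < 0 for v in w.values()):
        raise AllocationError("weights must be non-negative")
    total_w = sum(w.values())
    if total_w <= 0:
        raise AllocationError("all-zero allocation weights")
    out = {centre: 0.0 for centre in w}
    for item in item_totals:
        if item < 0:
            raise DomainError("shared item totals must be >= 0")
        for centre, weight in w.items():
            out[centre] += item * weight / total_w
    return out


@dataclass
class CostingResult:
    """Tidy cost table plus the log of centres excluded from comparisons."""

    costs: pd.DataFrame  # facility_id, specialty, centre_kind, metric, F, V, N, unit_cost
    dropped: list = field(default_factory=list)  # (facility_id, specialty, centre, reason)


def _annualized_amount(row: pd.Series, discount_rate: float) -> float:
    if not pd.isna(row["annual_recurrent_cost"]):
        return float(row["annual_recurrent_cost"])
    frac = row["apportion_fraction"]
    frac = 1.0 if pd.isna(frac) else float(frac)
    return (
        annualize_capital(float(row["purchase_price"]), float(row["useful_life_years"]), discount_rate)
        * frac
    )


_METRIC_PLAN = {
    CentreKind.OP: ((Metric.PER_VISIT, "opd_visits"),),
    CentreKind.IP: ((Metric.PER_ADMISSION, "admissions"), (Metric.PER_BED_DAY, "bed_days")),
    CentreKind.ICU: (
        (Metric.PER_ADMISSION, "icu_admissions"),
        (Metric.PER_BED_DAY, "icu_bed_days"),
    ),
    CentreKind.OT: ((Metric.PER_PROCEDURE, "procedures"),),
}


def compute_centre_costs(
    line_items: pd.DataFrame,
    utilization: pd.DataFrame,
    discount_rate: float = 0.03,
    shared_weights: Optional[Mapping[tuple[str, str, str], float]] = None,
) -> CostingResult:
    """Annual F, V and unit cost per (facility, specialty, centre, metric).

    Facility-level SHARED items are apportioned across the facility's centres
    top-down; the default allocation basis is each centre's annual service
    output (overridable via ``shared_weights`` keyed by
    (facility_id, specialty, centre_kind)). Centres whose denominator is zero
    while costs are positive are excluded and logged, not imputed.
    """
    items = line_items.copy()
    items["annualized"] = items.apply(_annualized_amount, axis=1, args=(discount_rate,))
    items["cost_class"] = [classify_cost(c).value for c in items["category"]]

    util = utilization.copy()
    util["bed_days"] = util["admissions"] * util["alos_days"]
    util["icu_bed_days"] = (util["icu_admissions"] * util["icu_alos_days"]).fillna(0.0)
    util_ix = util.set_index(["facility_id", "specialty"])

    centre_items = items[items["centre_kind"] != CentreKind.SHARED.value]
    shared_items = items[items["centre_kind"] == CentreKind.SHARED.value]

    totals = (
        centre_items.groupby(["facility_id", "specialty", "centre_kind", "cost_class"])[
            "annualized"
        ]
        .sum()
        .unstack("cost_class", fill_value=0.0)
        .reindex(columns=["fixed", "variable"], fill_value=0.0)
        .reset_index()
    )

    # Top-down apportionment of the facility-level shared pool.
    if not shared_items.empty:
        add_fixed: dict[tuple, float] = {}
        add_var: dict[tuple, float] = {}
        for fid, fac_shared in shared_items.groupby("facility_id"):
            fac_centres = totals[totals["facility_id"] == fid]
            if fac_centres.empty:
                raise AllocationError(f"shared items for {fid} but no centres to allocate to")
            keys = [
                (r.facility_id, r.specialty, r.centre_kind)
                for r in fac_centres.itertuples()
            ]
            if shared_weights is not None:
                weights = {k: float(shared_weights.get(k, 0.0)) for k in keys}
            else:
                weights = {}
                for k in keys:
                    _, spec, centre = k
                    urow = util_ix.loc[(fid, spec)]
                    basis = {
                        CentreKind.OP.value: "opd_visits",
                        CentreKind.IP.value: "bed_days",
                        CentreKind.ICU.value: "icu_bed_days",
                        CentreKind.OT.value: "procedures",
                    }[centre]
                    weights[k] = float(urow[basis])
            wkeys = {str(i): k for i, k in enumerate(keys)}
            wmap = {s: weights[k] for s, k in wkeys.items()}
            for cls, sink in (("fixed", add_fixed), ("variable", add_var)):
                cls_total = fac_shared.loc[fac_shared["cost_class"] == cls, "annualized"].sum()
                if cls_total > 0:
                    alloc = apportion_shared([cls_total], wmap)
                    for s, amount in alloc.items():
                        k = wkeys[s]
                        sink[k] = sink.get(k, 0.0) + amount
        for col, add in (("fixed", add_fixed), ("variable", add_var)):
            if add:
                key_series = list(zip(totals["facility_id"], totals["specialty"], totals["centre_kind"]))
                totals[col] = totals[col] + [add.get(k, 0.0) for k in key_series]

    rows = []
    dropped = []
    for r in totals.itertuples():
        key = (r.facility_id, r.specialty)
        if key not in util_ix.index:
            dropped.append((r.facility_id, r.specialty, r.centre_kind, "no_utilization"))
            continue
        urow = util_ix.loc[key]
        for metric, ucol in _METRIC_PLAN[CentreKind(r.centre_kind)]:
            n = float(urow[ucol]) if not pd.isna(urow[ucol]) else 0.0
            if n <= 0:
                if r.fixed + r.variable > 0:
                    dropped.append(
                        (r.facility_id, r.specialty, r.centre_kind, f"zero_output:{metric.value}")
                    )
                continue
            rows.append(
                (
                    r.facility_id,
                    r.specialty,
                    r.centre_kind,
                    metric.value,
                    r.fixed,
                    r.variable,
                    n,
                    (r.fixed + r.variable) / n,
                )
            )

    costs = pd.DataFrame(
        rows,
        columns=[
            "facility_id",
            "specialty",
            "centre_kind",
            "metric",
            "fixed_total",
            "variable_total",
            "output",
            "unit_cost",
        ],
    )
    return CostingResult(costs=costs, dropped=dropped)


def compute_procedure_cost(
    bottom_up_items: Iterable[tuple[float, float]],
    top_down_fixed: float,
    top_down_variable: float,
    procedures: float,
) -> dict[str, float]:
    """Mixed costing of a surgical procedure.

    ``bottom_up_items`` are per-procedure (quantity, unit price) pairs
    captured bottom-up (drugs, consumables, equipment use); human resources,
    infrastructure, furniture and overheads arrive as top-down annual shares.
    Returns annual F, V and the per-procedure unit cost; the fixed/variable
    split is retained for occupancy standardization.
    """
    if procedures <= 0:
        raise DomainError("procedures must be > 0 for a per-procedure unit cost")
    per_proc = 0.0
    for qty, price in bottom_up_items:
        if qty < 0 or price < 0:
            raise DomainError("bottom-up quantities and prices must be >= 0")
        per_proc += qty * price
    if top_down_fixed < 0 or top_down_variable < 0:
        raise DomainError("top-down shares must be >= 0")
    fixed_total = top_down_fixed
    variable_total = top_down_variable + per_proc * procedures
    return {
        "fixed_total": fixed_total,
        "variable_total": variable_total,
        "output": float(procedures),
        "unit_cost": (fixed_total + variable_total) / procedures,
    }
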