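"""Bed-occupancy standardization of unit costs.

Observed unit costs confound the cost structure with how intensively capacity
was used in the data year. To compare centres on an equal footing, the
service denominator is rescaled to a reference bed occupancy (80% and 100%
of capacity): variable costs move with utilization, fixed costs stay put.
With bed occupancy rate b and target t, the denominator becomes N* = N·t/b
and the adjusted unit cost is

    (F·b/t + V) / N  =  F·b / (t·N) + V / N

so the variable unit-cost component V/N is invariant and only the fixed
component is rescaled by b/t. The adjusted cost equals the unadjusted cost
exactly when b = t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .types import CentreKind, Metric


def bed_occupancy(
    beds: float, admissions: float, alos: float, days_per_year: float = 365.0
) -> float:
    """Bed occupancy rate: occupied bed-days over available bed-days.

    BOR = admissions × ALOS / (beds × days in year). May exceed 1 when wards
    run over capacity (extra beds in corridors, double occupancy).
    """
    if beds <= 0:
        raise DomainError(f"beds must be > 0 to compute occupancy, got {beds}")
    if admissions < 0 or alos < 0:
        raise DomainError("admissions and alos must be >= 0")
    if days_per_year <= 0:
        raise DomainError("days_per_year must be > 0")
    return admissions * alos / (beds * days_per_year)


def standardize_unit_cost(
    fixed_total: float, variable_total: float, output: float, bor: float, target: float
) -> float:
    """Unit cost re-expressed at the reference occupancy ``target``.

    Computed as (F·(bor/target) + V)/N, which is exactly (F+V)/N when
    bor == target and exactly V/N when F == 0.
    """
    if output <= 0:
        raise DomainError(f"output must be > 0, got {output}")
    if bor <= 0:
        raise DomainError(f"bed occupancy must be > 0, got {bor}")
    if target <= 0:
        raise DomainError(f"target occupancy must be > 0, got {target}")
    if fixed_total < 0 or variable_total < 0:
        raise DomainError("cost totals must be >= 0")
    return (fixed_total * (bor / target) + variable_total) / output


@dataclass
class StandardizationResult:
    table: pd.DataFrame
    skipped: list = field(default_factory=list)  # (facility, specialty, centre, reason)


def standardize_dataset(
    costs: pd.DataFrame,
    utilization: pd.DataFrame,
    targets: tuple[float, ...] = (0.8, 1.0),
    days_per_year: float = 365.0,
    bor_stability_floor: float = 0.05,
) -> StandardizationResult:
    """Standardize a tidy cost table at each target occupancy.

    IP metrics use the specialty's inpatient BOR; ICU metrics use the ICU's
    own BOR; OP and OT centres have no bed denominator of their own, so their
    utilization is scaled by the same specialty-level inpatient BOR ratio.
    Rows whose occupancy is missing or zero are skipped and logged; rows with
    bor below ``bor_stability_floor`` are standardized but flagged, since the
    fixed-cost rescaling factor bor/target becomes unstable there.
    """
    util = utilization.set_index(["facility_id", "specialty"])

    def occupancy_for(fid: str, spec: str, centre: str) -> float | None:
        try:
            row = util.loc[(fid, spec)]
        except KeyError:
            return None
        if centre == CentreKind.ICU.value:
            beds, adm, alos = row["icu_beds"], row["icu_admissions"], row["icu_alos_days"]
        else:
            beds, adm, alos = row["beds"], row["admissions"], row["alos_days"]
        if pd.isna(beds) or beds <= 0 or pd.isna(adm) or pd.isna(alos):
            return None
        return bed_occupancy(beds, adm, alos, days_per_year)

    rows = []
    skipped = []
    tcols = {t: f"adjusted_{int(round(t * 100))}" for t in targets}
    for r in costs.itertuples():
        bor = occupancy_for(r.facility_id, r.specialty, r.centre_kind)
        if bor is None or bor <= 0:
            skipped.append((r.facility_id, r.specialty, r.centre_kind, "missing_occupancy"))
            continue
        rec = {
            "facility_id": r.facility_id,
            "specialty": r.specialty,
            "centre_kind": r.centre_kind,
            "metric": r.metric,
            "fixed_total": r.fixed_total,
            "variable_total": r.variable_total,
            "output": r.output,
            "bor": bor,
            "unadjusted": r.unit_cost,
            "unstable_bor": bor < bor_stability_floor,
        }
        for t, col in tcols.items():
            rec[col] = standardize_unit_cost(
                r.fixed_total, r.variable_total, r.output, bor, t
            )
        rows.append(rec)

    table = pd.DataFrame(rows)
    return StandardizationResult(table=table, skipped=skipped)
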