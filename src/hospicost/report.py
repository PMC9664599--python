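"""Presentation rules and text report rendering.

Rounding is applied only here, at report time: INR to whole rupees; USD to
two decimals below 10 dollars and whole dollars otherwise (mirroring the
mixed precision of published cost tables); p-values to four decimals, with
very small values shown as "< 0.0005".
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .stats import DEFAULT_USD_RATE, inr_to_usd
from .types import GroupComparison, ScaleCorrelation


def format_inr(value: float) -> str:
    return f"{value:,.0f}"


def format_usd(value: float) -> str:
    if abs(value) < 10:
        return f"{value:.2f}"
    return f"{value:.0f}"


def format_p(p: float) -> str:
    if p < 0.0005:
        return "< 0.0005"
    return f"{p:.4f}"


def format_inr_usd(inr: float, usd_rate: float = DEFAULT_USD_RATE) -> str:
    return f"₹ {format_inr(inr)} ({format_usd(inr_to_usd(inr, usd_rate))} USD)"


def render_group_comparison(comp: GroupComparison, usd_rate: float = DEFAULT_USD_RATE) -> str:
    lines = [
        f"Outcome: {comp.outcome}  grouped by {comp.grouping}",
        f"{'group':<12}{'n':>6}{'median':>14}{'IQ range':>26}{'median USD':>12}",
    ]
    for g in comp.groups:
        iqr = f"({format_inr(g.q1)}-{format_inr(g.q3)})"
        lines.append(
            f"{g.group:<12}{g.n:>6}{format_inr(g.median):>14}{iqr:>26}"
            f"{format_usd(inr_to_usd(g.median, usd_rate)):>12}"
        )
    lines.append(
        f"Kruskal-Wallis H = {comp.H:.3f}, p = {format_p(comp.p)}, "
        f"eta2 = {comp.eta2:.4f} ({comp.effect_label}), k = {comp.k}, n = {comp.n_total}"
    )
    return "\n".join(lines)


def render_scale_correlation(sc: ScaleCorrelation) -> str:
    return (
        f"{sc.y} vs {sc.x}: r = {sc.r:.3f}, p = {format_p(sc.p)}, n = {sc.n} "
        f"(LOWESS span {sc.span:.2f}, {len(sc.curve_x)} curve points)"
    )


def render_report(
    comparisons: Iterable[GroupComparison],
    correlations: Iterable[ScaleCorrelation] = (),
    usd_rate: float = DEFAULT_USD_RATE,
) -> str:
    """Assemble the full text report: group comparison tables, then the
    cost–scale correlation summary."""
    blocks = [render_group_comparison(c, usd_rate) for c in comparisons]
    scale_lines = [render_scale_correlation(s) for s in correlations]
    if scale_lines:
        blocks.append("Scale analysis\n" + "\n".join(scale_lines))
    return ("\n\n".join(blocks)) + "\n"


def profile_table(utilization: pd.DataFrame, facilities: pd.DataFrame) -> pd.DataFrame:
    """Sample-profile summary: median (IQR) of beds, ALOS and bed occupancy
    per provider type and per city tier, inpatient cost centre."""
    from .standardize import bed_occupancy

    df = utilization.merge(
        facilities[["facility_id", "provider_type", "city_tier"]], on="facility_id"
    )
    df = df[df["beds"] > 0].copy()
    df["bed_occupancy"] = [
        bed_occupancy(b, a, l) for b, a, l in zip(df["beds"], df["admissions"], df["alos_days"])
    ]
    rows = []
    for grouping in ("provider_type", "city_tier"):
        for name, sub in df.groupby(grouping):
            rec = {"grouping": grouping, "group": name, "n": len(sub)}
            for col in ("beds", "alos_days", "bed_occupancy"):
                q1, med, q3 = sub[col].quantile([0.25, 0.5, 0.75])
                rec[f"{col}_median"] = med
                rec[f"{col}_q1"] = q1
                rec[f"{col}_q3"] = q3
            rows.append(rec)
    return pd.DataFrame(rows)
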