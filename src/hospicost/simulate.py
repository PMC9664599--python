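"""Seeded synthetic multi-site hospital facility data.

The generator emulates the structure of an Indian multi-site facility costing
sample: district, private and tertiary hospitals in tier-1/2/3 cities, each
with several specialties; every specialty has outpatient (OP) and inpatient
(IP) cost centres and, with configured probability, an intensive-care (ICU)
and operating-theatre (OT) centre. Capacity (beds), average length of stay
and bed occupancy are log-normal around configured medians — the medians are
the calibration contract, and the log-normal makes median targeting exact.
Resource use is emitted as annual line items per centre (salaries, capital
blocks for space/equipment/furniture, and volume-scaled variable inputs), so
the downstream costing engine sees the same shape of data a field study
collects.

Economies of scale are built in: fixed costs of inpatient-type centres are
scaled by (volume / type-median volume)**elasticity with elasticity < 0, so
average fixed cost per bed-day falls convexly with admissions, the pattern a
LOWESS fit picks up that a straight line does not.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import Category, CentreKind, FIXED_CATEGORIES, ProviderType

STATES = (
    "Jammu & Kashmir",
    "New Delhi",
    "Rajasthan",
    "Uttar Pradesh",
    "Bihar",
    "West Bengal",
    "Odisha",
    "Gujarat",
    "Maharashtra",
    "Andhra Pradesh",
    "Tamil Nadu",
)

SPECIALTIES = (
    "General Medicine",
    "General Surgery",
    "Obstetrics & Gynaecology",
    "Paediatrics",
    "Orthopaedics",
    "Ophthalmology",
    "ENT",
    "Dermatology",
    "Psychiatry",
    "Pulmonary Medicine",
    "Urology",
    "Neurology",
)

# How a centre's fixed and variable annual totals are split into line items.
# Fixed: salaries recurrent; space/equipment/furniture as capital blocks.
FIXED_SPLIT = {
    Category.HUMAN_RESOURCES: 0.55,
    Category.SPACE: 0.25,
    Category.EQUIPMENT: 0.15,
    Category.FURNITURE: 0.05,
}
VARIABLE_SPLIT = {
    Category.DRUGS: 0.40,
    Category.CONSUMABLES: 0.25,
    Category.UTILITIES: 0.10,
    Category.STATIONERY: 0.05,
    Category.MAINTENANCE: 0.10,
    Category.OVERHEADS: 0.10,
}
CAPITAL_LIVES = {Category.SPACE: 30.0, Category.EQUIPMENT: 10.0, Category.FURNITURE: 10.0}


@dataclass(frozen=True)
class ProviderParams:
    """Per-provider-type generative block.

    Medians and multiplicative spreads (sigma = SD of log values) parameterize
    log-normals; cost bases are annual INR totals at the type's median
    capacity and occupancy, so the configured medians are also the cost
    calibration points.
    """

    beds_median: float
    beds_sigma: float
    alos_median: float
    alos_sigma: float
    occupancy_median: float
    occupancy_sigma: float
    icu_beds_median: float
    icu_alos_median: float
    icu_occupancy_median: float
    opd_visits_mean: float
    procedures_mean: float
    ip_fixed_base: float  # INR/yr at median beds & occupancy
    ip_variable_per_bed_day: float  # INR per bed-day
    icu_fixed_base: float
    icu_variable_per_bed_day: float
    op_fixed_base: float
    op_variable_per_visit: float
    ot_fixed_base: float
    ot_bottom_up_per_procedure: float  # drugs/consumables/equipment per surgery
    specialties_range: tuple[int, int]
    tier_probs: tuple[float, float, float]  # P(tier 1), P(tier 2), P(tier 3)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_district: int = 27
    n_private: int = 16
    n_tertiary: int = 11
    district: ProviderParams = None  # type: ignore[assignment]
    private: ProviderParams = None  # type: ignore[assignment]
    tertiary: ProviderParams = None  # type: ignore[assignment]
    icu_fraction: float = 45.0 / 327.0
    ot_fraction: float = 219.0 / 327.0
    scale_elasticity: float = -0.3
    tier_multipliers: tuple[float, float, float] = (1.3, 1.2, 1.0)
    occupancy_ceiling: float = 2.0
    volume_sigma: float = 0.8  # spread of OPD visits / procedures around the mean
    cost_noise_sigma: float = 0.25  # residual noise on centre cost totals
    shared_fraction: float = 0.08  # facility-level shared pool vs centre totals
    days_per_year: float = 365.0
    discount_rate: float = 0.03  # used to price capital blocks consistently

    def params_for(self, provider_type: ProviderType) -> ProviderParams:
        return {
            ProviderType.DISTRICT: self.district,
            ProviderType.PRIVATE: self.private,
            ProviderType.TERTIARY: self.tertiary,
        }[provider_type]

    def validate(self) -> None:
        for name in ("n_district", "n_private", "n_tertiary"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not self.scale_elasticity < 0:
            raise ConfigurationError("scale_elasticity must be < 0")
        for frac_name in ("icu_fraction", "ot_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{frac_name} must be in [0, 1]")
        if self.occupancy_ceiling <= 0:
            raise ConfigurationError("occupancy_ceiling must be > 0")
        if any(m <= 0 for m in self.tier_multipliers):
            raise ConfigurationError("tier_multipliers must be > 0")
        for tname in ("district", "private", "tertiary"):
            p = getattr(self, tname)
            if p is None:
                raise ConfigurationError(f"{tname} parameter block missing")
            for fname, val in asdict(p).items():
                if fname in ("specialties_range", "tier_probs"):
                    continue
                if fname.endswith("_sigma") or "variable" in fname or "bottom_up" in fname:
                    # spreads and variable-cost rates may be zero (pure-fixed case)
                    if val < 0:
                        raise ConfigurationError(f"{tname}.{fname} must be >= 0")
                elif val <= 0:
                    raise ConfigurationError(f"{tname}.{fname} must be > 0")
            lo, hi = p.specialties_range
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{tname}.specialties_range invalid")
            if abs(sum(p.tier_probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{tname}.tier_probs must sum to 1")


@dataclass
class SyntheticDataset:
    """The three pipeline input tables plus the generating config (truth)."""

    facilities: pd.DataFrame
    line_items: pd.DataFrame
    utilization: pd.DataFrame
    truth: Optional[GeneratorConfig] = None

    def copy(self) -> "SyntheticDataset":
        return SyntheticDataset(
            facilities=self.facilities.copy(),
            line_items=self.line_items.copy(),
            utilization=self.utilization.copy(),
            truth=self.truth,
        )


def default_study_config(seed: int = 0) -> GeneratorConfig:
    """Generator configuration calibrated to the multi-site sample profile.

    Provider-type medians: beds 27/6/52, ALOS 4.3/2.5/5.8 days and IP bed
    occupancy 0.8/0.5/0.7 for district/private/tertiary; ICU occupancy
    0.7/0.2/0.8. Mean annual OPD consultations per specialty 17,250 / 1,142 /
    48,866 and surgical procedures 461 / 269 / 2,389. Spreads are set from
    the reported interquartile ranges of the log-normal marginals. Cost bases
    put the unadjusted median unit costs near the reported levels (e.g.
    per-bed-day roughly 819/1882/995 INR for district/private/tertiary).
    """
    district = ProviderParams(
        beds_median=27.0,
        beds_sigma=0.85,
        alos_median=4.3,
        alos_sigma=0.28,
        occupancy_median=0.8,
        occupancy_sigma=1.0,
        icu_beds_median=14.0,
        icu_alos_median=4.6,
        icu_occupancy_median=0.7,
        opd_visits_mean=17250.0,
        procedures_mean=461.0,
        ip_fixed_base=3.94e6,
        ip_variable_per_bed_day=320.0,
        icu_fixed_base=5.37e6,
        icu_variable_per_bed_day=1037.0,
        op_fixed_base=2.0e6,
        op_variable_per_visit=70.0,
        ot_fixed_base=1.27e6,
        ot_bottom_up_per_procedure=1500.0,
        specialties_range=(6, 9),
        tier_probs=(0.05, 0.20, 0.75),
    )
    private = ProviderParams(
        beds_median=6.0,
        beds_sigma=0.9,
        alos_median=2.5,
        alos_sigma=0.27,
        occupancy_median=0.5,
        occupancy_sigma=0.87,
        icu_beds_median=10.5,
        icu_alos_median=3.0,
        icu_occupancy_median=0.2,
        opd_visits_mean=1142.0,
        procedures_mean=269.0,
        ip_fixed_base=1.31e6,
        ip_variable_per_bed_day=682.0,
        icu_fixed_base=6.13e6,
        icu_variable_per_bed_day=2619.0,
        op_fixed_base=1.3e6,
        op_variable_per_visit=120.0,
        ot_fixed_base=1.07e6,
        ot_bottom_up_per_procedure=3000.0,
        specialties_range=(4, 6),
        tier_probs=(0.20, 0.50, 0.30),
    )
    tertiary = ProviderParams(
        beds_median=52.0,
        beds_sigma=0.71,
        alos_median=5.8,
        alos_sigma=0.28,
        occupancy_median=0.7,
        occupancy_sigma=0.8,
        icu_beds_median=18.0,
        icu_alos_median=2.0,
        icu_occupancy_median=0.8,
        opd_visits_mean=48866.0,
        procedures_mean=2389.0,
        ip_fixed_base=6.64e6,
        ip_variable_per_bed_day=495.0,
        icu_fixed_base=18.4e6,
        icu_variable_per_bed_day=2531.0,
        op_fixed_base=10.0e6,
        op_variable_per_visit=100.0,
        ot_fixed_base=16.6e6,
        ot_bottom_up_per_procedure=3500.0,
        specialties_range=(3, 6),
        tier_probs=(0.30, 0.40, 0.30),
    )
    return GeneratorConfig(seed=seed, district=district, private=private, tertiary=tertiary)


def _facility_rng(master_seed: int, facility_id: str) -> np.random.Generator:
    """One stream per facility, keyed by a stable hash of the id so that
    insertion order cannot change the draws."""
    return np.random.default_rng([master_seed, zlib.crc32(facility_id.encode("utf-8"))])


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def _annuity_factor(rate: float, life: float) -> float:
    if rate == 0:
        return life
    return (1.0 - (1.0 + rate) ** (-life)) / rate


_LINE_ITEM_COLUMNS = [
    "facility_id",
    "specialty",
    "centre_kind",
    "category",
    "annual_recurrent_cost",
    "purchase_price",
    "useful_life_years",
    "apportion_fraction",
    "quantity_basis",
]

_UTILIZATION_COLUMNS = [
    "facility_id",
    "specialty",
    "beds",
    "admissions",
    "alos_days",
    "icu_beds",
    "icu_admissions",
    "icu_alos_days",
    "opd_visits",
    "procedures",
]


def _emit_centre_items(
    rows: list,
    facility_id: str,
    specialty: str,
    centre: CentreKind,
    fixed_total: float,
    variable_total: float,
    discount_rate: float,
) -> None:
    """Split centre totals into category line items.

    Capital categories are written as purchase blocks priced so that the
    annuity annualization at the generator's discount rate recovers the
    intended annual cost exactly.
    """
    for cat, share in FIXED_SPLIT.items():
        annual = fixed_total * share
        if cat in CAPITAL_LIVES:
            life = CAPITAL_LIVES[cat]
            price = annual * _annuity_factor(discount_rate, life)
            rows.append(
                (facility_id, specialty, centre.value, cat.value, np.nan, price, life, 1.0, np.nan)
            )
        else:
            rows.append(
                (facility_id, specialty, centre.value, cat.value, annual, np.nan, np.nan, np.nan, np.nan)
            )
    for cat, share in VARIABLE_SPLIT.items():
        rows.append(
            (
                facility_id,
                specialty,
                centre.value,
                cat.value,
                variable_total * share,
                np.nan,
                np.nan,
                np.nan,
                np.nan,
            )
        )


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a seeded multi-site facility dataset.

    Deterministic given the config (which carries the seed). Per-provider-type
    empirical medians of beds, ALOS and occupancy converge to the configured
    medians as the number of centres grows; ICU and OT centres appear in the
    configured fractions of specialties. Economies of scale are injected via
    :func:`inject_scale_structure` at ``config.scale_elasticity``.
    """
    config.validate()

    fac_rows: list = []
    item_rows: list = []
    util_rows: list = []

    plan = [
        (ProviderType.DISTRICT, config.n_district, "DH"),
        (ProviderType.PRIVATE, config.n_private, "PVT"),
        (ProviderType.TERTIARY, config.n_tertiary, "TER"),
    ]
    for ptype, n_fac, prefix in plan:
        params = config.params_for(ptype)
        for i in range(n_fac):
            fid = f"{prefix}-{i + 1:03d}"
            rng = _facility_rng(config.seed, fid)
            tier = int(rng.choice([1, 2, 3], p=params.tier_probs))
            state = str(rng.choice(STATES))
            tier_mult = config.tier_multipliers[tier - 1]
            lo, hi = params.specialties_range
            n_spec = int(rng.integers(lo, hi + 1))
            spec_names = list(rng.choice(SPECIALTIES, size=n_spec, replace=False))

            fac_fixed_total = 0.0
            fac_variable_total = 0.0
            fac_item_rows: list = []

            for spec in spec_names:
                beds = max(1, int(round(_lognormal(rng, params.beds_median, params.beds_sigma))))
                alos = _lognormal(rng, params.alos_median, params.alos_sigma)
                occ = min(
                    _lognormal(rng, params.occupancy_median, params.occupancy_sigma),
                    config.occupancy_ceiling,
                )
                admissions = max(1, int(round(occ * beds * config.days_per_year / alos)))
                bed_days = admissions * alos

                opd_visits = max(
                    1,
                    int(
                        round(
                            _lognormal(
                                rng,
                                params.opd_visits_mean
                                * np.exp(-0.5 * config.volume_sigma**2),
                                config.volume_sigma,
                            )
                        )
                    ),
                )

                has_icu = rng.random() < config.icu_fraction
                has_ot = rng.random() < config.ot_fraction

                noise = lambda: float(np.exp(config.cost_noise_sigma * rng.standard_normal()))

                # IP centre: fixed scales with capacity, variable with bed-days.
                f_ip = params.ip_fixed_base * (beds / params.beds_median) * tier_mult * noise()
                v_ip = params.ip_variable_per_bed_day * bed_days * tier_mult * noise()
                _emit_centre_items(
                    fac_item_rows, fid, spec, CentreKind.IP, f_ip, v_ip, config.discount_rate
                )

                f_op = params.op_fixed_base * tier_mult * noise()
                v_op = params.op_variable_per_visit * opd_visits * tier_mult * noise()
                _emit_centre_items(
                    fac_item_rows, fid, spec, CentreKind.OP, f_op, v_op, config.discount_rate
                )

                icu_beds = icu_adm = 0
                icu_alos = np.nan
                if has_icu:
                    icu_beds = max(1, int(round(_lognormal(rng, params.icu_beds_median, 0.4))))
                    icu_alos = _lognormal(rng, params.icu_alos_median, 0.3)
                    icu_occ = min(
                        _lognormal(rng, params.icu_occupancy_median, 0.6),
                        config.occupancy_ceiling,
                    )
                    icu_adm = max(
                        1, int(round(icu_occ * icu_beds * config.days_per_year / icu_alos))
                    )
                    icu_bed_days = icu_adm * icu_alos
                    f_icu = (
                        params.icu_fixed_base
                        * (icu_beds / params.icu_beds_median)
                        * tier_mult
                        * noise()
                    )
                    v_icu = (
                        params.icu_variable_per_bed_day * icu_bed_days * tier_mult * noise()
                    )
                    _emit_centre_items(
                        fac_item_rows, fid, spec, CentreKind.ICU, f_icu, v_icu, config.discount_rate
                    )

                procedures = 0
                if has_ot:
                    procedures = max(
                        1,
                        int(
                            round(
                                _lognormal(
                                    rng,
                                    params.procedures_mean
                                    * np.exp(-0.5 * config.volume_sigma**2),
                                    config.volume_sigma,
                                )
                            )
                        ),
                    )
                    f_ot = params.ot_fixed_base * tier_mult * noise()
                    v_ot = (
                        params.ot_bottom_up_per_procedure * procedures * tier_mult * noise()
                    )
                    _emit_centre_items(
                        fac_item_rows, fid, spec, CentreKind.OT, f_ot, v_ot, config.discount_rate
                    )

                util_rows.append(
                    (
                        fid,
                        spec,
                        beds,
                        admissions,
                        alos,
                        icu_beds,
                        icu_adm,
                        icu_alos,
                        opd_visits,
                        procedures,
                    )
                )

            # Facility-level shared pool, apportioned top-down by the engine:
            # administration salaries (fixed) and facility overheads (variable).
            for r in fac_item_rows:
                cat = Category(r[3])
                annual = r[4] if not pd.isna(r[4]) else r[5] / _annuity_factor(
                    config.discount_rate, r[6]
                )
                if cat in FIXED_CATEGORIES:
                    fac_fixed_total += annual
                else:
                    fac_variable_total += annual
            if spec_names:
                fac_item_rows.append(
                    (
                        fid,
                        "",
                        CentreKind.SHARED.value,
                        Category.HUMAN_RESOURCES.value,
                        config.shared_fraction * fac_fixed_total,
                        np.nan,
                        np.nan,
                        np.nan,
                        np.nan,
                    )
                )
                fac_item_rows.append(
                    (
                        fid,
                        "",
                        CentreKind.SHARED.value,
                        Category.OVERHEADS.value,
                        config.shared_fraction * fac_variable_total,
                        np.nan,
                        np.nan,
                        np.nan,
                        np.nan,
                    )
                )

            item_rows.extend(fac_item_rows)
            fac_rows.append((fid, ptype.value, tier, state, "|".join(spec_names)))

    facilities = pd.DataFrame(
        fac_rows, columns=["facility_id", "provider_type", "city_tier", "state", "specialties"]
    )
    line_items = pd.DataFrame(item_rows, columns=_LINE_ITEM_COLUMNS)
    utilization = pd.DataFrame(util_rows, columns=_UTILIZATION_COLUMNS)

    dataset = SyntheticDataset(
        facilities=facilities, line_items=line_items, utilization=utilization, truth=config
    )
    return inject_scale_structure(dataset, config.scale_elasticity)


def inject_scale_structure(dataset: SyntheticDataset, elasticity: float) -> SyntheticDataset:
    """Rescale inpatient-type fixed costs so average fixed cost falls with volume.

    Each IP/ICU centre's fixed line items are multiplied by
    ``(bed_days / reference_bed_days) ** elasticity`` where the reference is
    the provider type's configured median annual bed-days. With elasticity
    < 0 this makes cost per bed-day decrease convexly with admissions and
    occupancy while leaving each type's cost level at its calibration point.
    """
    if elasticity >= 0:
        raise ConfigurationError("elasticity must be < 0")
    if dataset.truth is None:
        raise ConfigurationError("dataset.truth config required to locate reference volumes")

    config = dataset.truth
    out = dataset.copy()

    ptype_by_fac = dict(
        zip(out.facilities["facility_id"], out.facilities["provider_type"])
    )
    util = out.utilization.set_index(["facility_id", "specialty"])

    def factor(fid: str, spec: str, centre: str) -> float:
        params = config.params_for(ProviderType(ptype_by_fac[fid]))
        row = util.loc[(fid, spec)]
        if centre == CentreKind.IP.value:
            bed_days = row["admissions"] * row["alos_days"]
            ref = (
                params.occupancy_median * params.beds_median * config.days_per_year
            )
        else:  # ICU
            bed_days = row["icu_admissions"] * row["icu_alos_days"]
            ref = (
                params.icu_occupancy_median
                * params.icu_beds_median
                * config.days_per_year
            )
        if bed_days <= 0:
            return 1.0
        return float((bed_days / ref) ** elasticity)

    items = out.line_items
    fixed_cats = {c.value for c in FIXED_CATEGORIES}
    mask = items["centre_kind"].isin([CentreKind.IP.value, CentreKind.ICU.value]) & items[
        "category"
    ].isin(fixed_cats)
    for idx in items.index[mask]:
        f = factor(
            items.at[idx, "facility_id"], items.at[idx, "specialty"], items.at[idx, "centre_kind"]
        )
        if not pd.isna(items.at[idx, "annual_recurrent_cost"]):
            items.at[idx, "annual_recurrent_cost"] *= f
        else:
            items.at[idx, "purchase_price"] *= f
    return out
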