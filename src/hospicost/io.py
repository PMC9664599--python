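"""Table schemas, validated CSV round-tripping, and pipeline configuration.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimal separator. Monetary fields are decimal rupees. The three pipeline
inputs are:

facilities.csv   facility_id, provider_type, city_tier, state, specialties
                 (specialties joined by "|")
line_items.csv   facility_id, specialty, centre_kind, category,
                 annual_recurrent_cost, purchase_price, useful_life_years,
                 apportion_fraction, quantity_basis
                 (exactly one of annual_recurrent_cost / capital block set;
                 SHARED rows have an empty specialty — facility level)
utilization.csv  facility_id, specialty, beds, admissions, alos_days,
                 icu_beds, icu_admissions, icu_alos_days, opd_visits,
                 procedures
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import IntegrityError, SchemaError
from .simulate import (
    GeneratorConfig,
    ProviderParams,
    SyntheticDataset,
    _LINE_ITEM_COLUMNS,
    _UTILIZATION_COLUMNS,
)
from .types import Category, CentreKind, ProviderType

FACILITY_COLUMNS = ["facility_id", "provider_type", "city_tier", "state", "specialties"]

SCHEMAS = {
    "facilities": FACILITY_COLUMNS,
    "line_items": _LINE_ITEM_COLUMNS,
    "utilization": _UTILIZATION_COLUMNS,
}


def _check_columns(df: pd.DataFrame, name: str) -> None:
    expected = SCHEMAS[name]
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{name}: schema mismatch; missing columns {missing}, extra columns {extra}"
        )


def write_tables(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three input tables (and the config, if present) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("facilities", dataset.facilities),
        ("line_items", dataset.line_items),
        ("utilization", dataset.utilization),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    if dataset.truth is not None:
        p = out / "generator_config.yaml"
        p.write_text(config_to_yaml(dataset.truth), encoding="utf-8")
        paths["config"] = p
    return paths


def read_tables(
    facilities_path: str | Path,
    line_items_path: str | Path,
    utilization_path: str | Path,
    config_path: Optional[str | Path] = None,
) -> SyntheticDataset:
    """Read and validate the three input tables.

    Enforces the documented schemas, closed enums, the exactly-one-of
    recurrent/capital rule, and referential integrity: every line-item and
    utilization row must join to a facility (SHARED rows join at facility
    level). Violations are reported with offending row numbers / keys.
    """
    for p in (facilities_path, line_items_path, utilization_path):
        if not Path(p).exists():
            raise SchemaError(f"input file not found: {p}")
    facilities = pd.read_csv(facilities_path, dtype={"facility_id": str})
    line_items = pd.read_csv(line_items_path, dtype={"facility_id": str})
    utilization = pd.read_csv(utilization_path, dtype={"facility_id": str})
    _check_columns(facilities, "facilities")
    _check_columns(line_items, "line_items")
    _check_columns(utilization, "utilization")

    line_items["specialty"] = line_items["specialty"].fillna("")
    facilities["specialties"] = facilities["specialties"].fillna("")

    if facilities["facility_id"].duplicated().any():
        dups = facilities.loc[facilities["facility_id"].duplicated(), "facility_id"].tolist()
        raise IntegrityError(f"duplicate facility_id values: {dups}")
    bad_types = set(facilities["provider_type"]) - {t.value for t in ProviderType}
    if bad_types:
        raise SchemaError(f"facilities: unknown provider_type values {sorted(bad_types)}")
    bad_tiers = set(facilities["city_tier"].astype(int)) - {1, 2, 3}
    if bad_tiers:
        raise SchemaError(f"facilities: city_tier outside 1-3: {sorted(bad_tiers)}")

    bad_centres = set(line_items["centre_kind"]) - {c.value for c in CentreKind}
    if bad_centres:
        raise SchemaError(f"line_items: unknown centre_kind values {sorted(bad_centres)}")
    bad_cats = set(line_items["category"]) - {c.value for c in Category}
    if bad_cats:
        raise SchemaError(f"line_items: unknown category values {sorted(bad_cats)}")

    has_recurrent = line_items["annual_recurrent_cost"].notna()
    has_capital = line_items["purchase_price"].notna()
    both = line_items.index[has_recurrent & has_capital].tolist()
    neither = line_items.index[~has_recurrent & ~has_capital].tolist()
    if both or neither:
        raise SchemaError(
            "line_items: exactly one of annual_recurrent_cost / purchase_price must "
            f"be set; both set at rows {both[:10]}, neither at rows {neither[:10]}"
        )
    cap = line_items[has_capital]
    if (cap["useful_life_years"] <= 0).any():
        raows = cap.index[cap["useful_life_years"] <= 0].tolist()
        raise SchemaError(f"line_items: useful_life_years must be > 0 at rows {raows[:10]}")
    frac = cap["apportion_fraction"].dropna()
    if ((frac < 0) | (frac > 1)).any():
        raise SchemaError("line_items: apportion_fraction must be in [0, 1]")
    money = pd.concat(
        [line_items["annual_recurrent_cost"].dropna(), cap["purchase_price"]]
    )
    if (money < 0).any():
        raise SchemaError("line_items: monetary values must be >= 0")

    known = set(facilities["facility_id"])
    for name, df in (("line_items", line_items), ("utilization", utilization)):
        orphans = sorted(set(df["facility_id"]) - known)
        if orphans:
            raise IntegrityError(f"{name}: orphan facility_id values {orphans}")

    util_keys = set(zip(utilization["facility_id"], utilization["specialty"]))
    non_shared = line_items[line_items["centre_kind"] != CentreKind.SHARED.value]
    item_keys = set(zip(non_shared["facility_id"], non_shared["specialty"]))
    orphan_keys = sorted(item_keys - util_keys)
    if orphan_keys:
        raise IntegrityError(
            f"line_items: centre keys without utilization rows: {orphan_keys[:10]}"
        )

    truth = config_from_yaml(Path(config_path).read_text(encoding="utf-8")) if config_path else None
    return SyntheticDataset(
        facilities=facilities, line_items=line_items, utilization=utilization, truth=truth
    )


def config_to_yaml(config: GeneratorConfig) -> str:
    return yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)


def config_from_yaml(text: str) -> GeneratorConfig:
    raw = yaml.safe_load(text)
    for block in ("district", "private", "tertiary"):
        if raw.get(block) is not None:
            p = dict(raw[block])
            p["specialties_range"] = tuple(p["specialties_range"])
            p["tier_probs"] = tuple(p["tier_probs"])
            raw[block] = ProviderParams(**p)
    raw["tier_multipliers"] = tuple(raw["tier_multipliers"])
    return GeneratorConfig(**raw)


def config_hash(config: GeneratorConfig) -> str:
    """Stable short hash of a config for run logging."""
    return hashlib.sha256(config_to_yaml(config).encode("utf-8")).hexdigest()[:12]
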