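"""Domain types for multi-site hospital costing.

The pipeline's tabular payloads travel as pandas DataFrames with documented
schemas (see :mod:`hospicost.io`); the dataclasses here carry structured
results and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class ProviderType(str, Enum):
    """Ownership/level of a sampled hospital."""

    DISTRICT = "district"
    PRIVATE = "private"
    TERTIARY = "tertiary"


class CentreKind(str, Enum):
    """Cost centre within a specialty.

    SHARED marks facility-level items apportioned across centres top-down.
    """

    OP = "OP"
    IP = "IP"
    ICU = "ICU"
    OT = "OT"
    SHARED = "SHARED"


class Category(str, Enum):
    """Resource input category; determines the fixed/variable class."""

    HUMAN_RESOURCES = "human_resources"
    SPACE = "space"
    EQUIPMENT = "equipment"
    FURNITURE = "furniture"
    DRUGS = "drugs"
    CONSUMABLES = "consumables"
    UTILITIES = "utilities"
    STATIONERY = "stationery"
    MAINTENANCE = "maintenance"
    OVERHEADS = "overheads"


class CostClass(str, Enum):
    FIXED = "fixed"
    VARIABLE = "variable"


class Metric(str, Enum):
    """Unit-cost denominator."""

    PER_VISIT = "per_visit"
    PER_ADMISSION = "per_admission"
    PER_BED_DAY = "per_bed_day"
    PER_PROCEDURE = "per_procedure"


#: Fixed categories: salaries plus annualized capital (space, equipment,
#: furniture). Equipment *maintenance* is variable even though the capital is
#: fixed; everything that scales with output volume is variable.
FIXED_CATEGORIES = frozenset(
    {Category.HUMAN_RESOURCES, Category.SPACE, Category.EQUIPMENT, Category.FURNITURE}
)
VARIABLE_CATEGORIES = frozenset(
    {
        Category.DRUGS,
        Category.CONSUMABLES,
        Category.UTILITIES,
        Category.STATIONERY,
        Category.MAINTENANCE,
        Category.OVERHEADS,
    }
)


@dataclass(frozen=True)
class CentreCost:
    """Annual cost of one cost centre for one unit-cost metric.

    F and V are annual fixed and variable totals (INR/yr); N is the annual
    service output in the metric's units. The unit cost (F+V)/N is defined
    only for N > 0.
    """

    facility_id: str
    specialty: str
    centre_kind: CentreKind
    metric: Metric
    fixed_total: float
    variable_total: float
    output: float

    @property
    def unit_cost(self) -> Optional[float]:
        if self.output <= 0:
            return None
        return (self.fixed_total + self.variable_total) / self.output


@dataclass(frozen=True)
class StandardizedUnitCost:
    """Unit cost re-expressed at a reference bed occupancy.

    Variable cost per unit is invariant under standardization; only the fixed
    component is rescaled by bor/target.
    """

    facility_id: str
    specialty: str
    centre_kind: CentreKind
    metric: Metric
    unadjusted: float
    adjusted_80: float
    adjusted_100: float
    bor: float
    unstable_bor: bool = False  # bor below the stability floor; values kept, flagged


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal–Wallis comparison of a unit-cost outcome across groups."""

    outcome: str
    grouping: str
    groups: tuple[GroupSummary, ...]
    H: float
    p: float
    k: int
    n_total: int
    eta2: float
    effect_label: str


@dataclass(frozen=True)
class ScaleCorrelation:
    """Pearson correlation of unit cost with a scale variable, plus the
    LOWESS-smoothed central-tendency curve for visual assessment."""

    y: str
    x: str
    r: float
    p: float
    n: int
    curve_x: tuple[float, ...]
    curve_y: tuple[float, ...]
    span: float


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    All monetary arithmetic is in INR at 2020 prices; USD is presentation
    only. Useful lives and the discount rate drive capital annualization.
    """

    discount_rate: float = 0.03
    useful_lives: dict = field(
        default_factory=lambda: {"space": 30.0, "equipment": 10.0, "furniture": 10.0}
    )
    targets: tuple[float, ...] = (0.8, 1.0)
    usd_rate: float = 76.21
    days_per_year: float = 365.0
    smoothing_span: float = 2.0 / 3.0
    bor_stability_floor: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        from .errors import ConfigurationError

        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")
        if self.usd_rate <= 0:
            raise ConfigurationError("usd_rate must be > 0")
        if any(t <= 0 for t in self.targets):
            raise ConfigurationError("targets must be > 0")
        if any(l <= 0 for l in self.useful_lives.values()):
            raise ConfigurationError("useful_lives must be > 0")
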