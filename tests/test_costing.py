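"""Costing engine: annualization, classification, apportionment, unit costs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hospicost import (
    annualize_capital,
    apportion_shared,
    classify_cost,
    compute_centre_costs,
    compute_procedure_cost,
)
from hospicost.errors import AllocationError, DomainError
from hospicost.types import Category, CostClass


class TestAnnualizeCapital:
    def test_zero_rate_is_straight_line(self):
        assert annualize_capital(1000, 10, 0.0) == pytest.approx(100.0)

    def test_zero_price(self):
        assert annualize_capital(0, 5, 0.1) == 0.0

    def test_annuity_value_hand_computed(self):
        # 100000 * 0.03 / (1 - 1.03^-10) = 11723.0506...
        assert annualize_capital(100000, 10, 0.03) == pytest.approx(11723.0506, abs=0.01)

    def test_nonpositive_life_rejected(self):
        with pytest.raises(DomainError):
            annualize_capital(1000, 0, 0.03)
        with pytest.raises(DomainError):
            annualize_capital(1000, -3, 0.03)

    @given(
        price=st.floats(0, 1e9),
        life=st.floats(0.5, 60),
        rate=st.floats(0, 0.2),
    )
    @settings(max_examples=200, deadline=None)
    def test_annualized_between_interest_and_full_replacement(self, price, life, rate):
        """The equivalent annual cost is at least the straight-line charge and
        approaches it as the rate goes to zero."""
        a = annualize_capital(price, life, rate)
        assert a >= price / life - 1e-9 * max(price, 1)


class TestClassifyCost:
    @pytest.mark.parametrize(
        "category, expected",
        [
            (Category.HUMAN_RESOURCES, CostClass.FIXED),
            (Category.SPACE, CostClass.FIXED),
            (Category.EQUIPMENT, CostClass.FIXED),
            (Category.FURNITURE, CostClass.FIXED),
            (Category.DRUGS, CostClass.VARIABLE),
            (Category.CONSUMABLES, CostClass.VARIABLE),
            (Category.UTILITIES, CostClass.VARIABLE),
            (Category.STATIONERY, CostClass.VARIABLE),
            (Category.MAINTENANCE, CostClass.VARIABLE),  # even though equipment is fixed
            (Category.OVERHEADS, CostClass.VARIABLE),
        ],
    )
    def test_mapping(self, category, expected):
        assert classify_cost(category) is expected
        assert classify_cost(category.value) is expected

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            classify_cost("helicopters")


class TestApportionShared:
    def test_proportionality(self):
        assert apportion_shared([900.0], {"A": 1.0, "B": 2.0}) == pytest.approx(
            {"A": 300.0, "B": 600.0}
        )

    def test_single_centre_identity(self):
        out = apportion_shared([1234.5], {"A": 0.7})
        assert out["A"] == pytest.approx(1234.5)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(AllocationError):
            apportion_shared([100.0], {"A": 0.0, "B": 0.0})

    def test_conservation_random_configurations(self):
        rng = np.random.default_rng(202)
        for _ in range(200):
            n_items = rng.integers(1, 5)
            n_centres = rng.integers(1, 6)
            items = rng.uniform(0, 1e7, n_items)
            weights = {f"c{j}": float(w) for j, w in enumerate(rng.uniform(0, 10, n_centres))}
            if sum(weights.values()) == 0:
                continue
            out = apportion_shared(items, weights)
            assert abs(sum(out.values()) - items.sum()) < 0.01


def _centre_tables(fixed, variable, beds=10, admissions=100, alos=4.0, visits=0):
    items = pd.DataFrame(
        {
            "facility_id": ["F1", "F1"],
            "specialty": ["Gen", "Gen"],
            "centre_kind": ["IP", "IP"],
            "category": ["human_resources", "drugs"],
            "annual_recurrent_cost": [fixed, variable],
            "purchase_price": [np.nan, np.nan],
            "useful_life_years": [np.nan, np.nan],
            "apportion_fraction": [np.nan, np.nan],
            "quantity_basis": [np.nan, np.nan],
        }
    )
    util = pd.DataFrame(
        {
            "facility_id": ["F1"],
            "specialty": ["Gen"],
            "beds": [beds],
            "admissions": [admissions],
            "alos_days": [alos],
            "icu_beds": [0],
            "icu_admissions": [0],
            "icu_alos_days": [np.nan],
            "opd_visits": [visits],
            "procedures": [0],
        }
    )
    return items, util


class TestComputeCentreCosts:
    def test_known_totals_match_hand_arithmetic(self):
        items, util = _centre_tables(fixed=8000.0, variable=2000.0, admissions=100, alos=4.0)
        res = compute_centre_costs(items, util)
        by_metric = res.costs.set_index("metric")
        assert by_metric.loc["per_admission", "unit_cost"] == pytest.approx(100.0)
        assert by_metric.loc["per_bed_day", "unit_cost"] == pytest.approx(25.0)
        assert by_metric.loc["per_admission", "fixed_total"] == pytest.approx(8000.0)
        assert by_metric.loc["per_admission", "variable_total"] == pytest.approx(2000.0)

    def test_bed_day_alos_identity(self, small_dataset):
        """per_bed_day × ALOS = per_admission, exactly, for every IP/ICU centre."""
        res = compute_centre_costs(small_dataset.line_items, small_dataset.utilization)
        costs = res.costs[res.costs.centre_kind.isin(["IP", "ICU"])]
        wide = costs.pivot_table(
            index=["facility_id", "specialty", "centre_kind"],
            columns="metric",
            values=["unit_cost", "output"],
        )
        alos = wide[("output", "per_bed_day")] / wide[("output", "per_admission")]
        np.testing.assert_allclose(
            wide[("unit_cost", "per_bed_day")] * alos,
            wide[("unit_cost", "per_admission")],
            rtol=1e-12,
        )

    def test_fully_variable_decomposition(self):
        items, util = _centre_tables(fixed=0.0, variable=1000.0, visits=100)
        items["centre_kind"] = "OP"
        res = compute_centre_costs(items, util)
        row = res.costs.iloc[0]
        assert row.metric == "per_visit"
        assert row.unit_cost == pytest.approx(10.0)
        assert row.fixed_total == 0.0

    def test_zero_output_dropped_and_logged(self):
        items, util = _centre_tables(fixed=5000.0, variable=0.0, visits=0)
        items["centre_kind"] = "OP"
        res = compute_centre_costs(items, util)
        assert res.costs.empty
        assert any("zero_output" in reason for *_, reason in res.dropped)

    def test_conservation_with_shared_items(self, small_dataset):
        """Total annual cost input equals the total attributed across centres
        (F + V), with no unallocated remainder."""
        from hospicost.costing import _annualized_amount

        res = compute_centre_costs(small_dataset.line_items, small_dataset.utilization)
        total_in = sum(
            _annualized_amount(row, 0.03) for _, row in small_dataset.line_items.iterrows()
        )
        total_attributed = (
            res.costs.drop_duplicates(["facility_id", "specialty", "centre_kind"])[
                ["fixed_total", "variable_total"]
            ]
            .to_numpy()
            .sum()
        )
        assert total_attributed == pytest.approx(total_in, rel=1e-9)

    def test_apportion_fraction_scales_capital(self):
        items, util = _centre_tables(fixed=0.0, variable=0.0)
        items = items.iloc[:1].copy()
        items["category"] = "equipment"
        items["annual_recurrent_cost"] = np.nan
        items["purchase_price"] = 1000.0
        items["useful_life_years"] = 10.0
        items["apportion_fraction"] = 0.5
        res = compute_centre_costs(items, util, discount_rate=0.0)
        assert res.costs.iloc[0].fixed_total == pytest.approx(50.0)  # 1000/10 * 0.5


class TestComputeProcedureCost:
    def test_bottom_up_only_volume_invariant(self):
        a = compute_procedure_cost([(2.0, 100.0), (1.0, 300.0)], 0.0, 0.0, 50)
        b = compute_procedure_cost([(2.0, 100.0), (1.0, 300.0)], 0.0, 0.0, 500)
        assert a["unit_cost"] == pytest.approx(500.0)
        assert b["unit_cost"] == pytest.approx(500.0)

    def test_mixed_cost_hand_arithmetic(self):
        out = compute_procedure_cost([(1.0, 500.0)], 100000.0, 0.0, 100)
        assert out["unit_cost"] == pytest.approx(1500.0)

    def test_fixed_share_dilutes_with_volume(self):
        lo = compute_procedure_cost([(1.0, 500.0)], 100000.0, 0.0, 100)
        hi = compute_procedure_cost([(1.0, 500.0)], 100000.0, 0.0, 200)
        assert hi["unit_cost"] < lo["unit_cost"]

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            compute_procedure_cost([(-1.0, 500.0)], 0.0, 0.0, 10)
        with pytest.raises(DomainError):
            compute_procedure_cost([(1.0, 500.0)], 0.0, 0.0, 0)
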