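"""Compute unadjusted unit costs per cost centre.

Reads the tables written by 01_simulate.py, annualizes capital at 3%/yr,
apportions facility-level shared costs top-down, and writes the tidy unit
cost table (one row per facility x specialty x centre x metric) to
results/unit_costs.csv. Prints the median unadjusted unit cost per centre
kind and metric.
"""

from pathlib import Path

from hospicost import compute_centre_costs
from hospicost.io import read_tables

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = ROOT / "data"
    dataset = read_tables(
        data / "facilities.csv", data / "line_items.csv", data / "utilization.csv"
    )
    result = compute_centre_costs(dataset.line_items, dataset.utilization, discount_rate=0.03)
    result.costs.to_csv(ROOT / "unit_costs.csv", index=False)

    print(f"{len(result.costs)} cost rows, {len(result.dropped)} centres dropped (zero output)")
    med = (
        result.costs.groupby(["centre_kind", "metric"])["unit_cost"]
        .median()
        .round(0)
        .rename("median_unit_cost_inr")
    )
    print(med.to_string())


if __name__ == "__main__":
    main()
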