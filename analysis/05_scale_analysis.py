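"""Economies of scale: cost vs activity in district hospitals.

Pearson correlations of the unadjusted IP per-bed-day / per-admission cost
with admissions, beds and bed occupancy (and OP per-visit cost with visit
volume), restricted to district hospitals for comparability, with LOWESS
curves to assess nonlinearity. Writes results/scale_curves.csv and
results/scale_correlations.csv; a convex, decreasing LOWESS curve with a
negative r is the economies-of-scale signature.
"""

from pathlib import Path

import pandas as pd

from hospicost.io import read_tables
from hospicost.pipeline import scale_analysis
from hospicost.report import render_scale_correlation

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = ROOT / "data"
    dataset = read_tables(
        data / "facilities.csv", data / "line_items.csv", data / "utilization.csv"
    )
    std = pd.read_csv(ROOT / "standardized.csv", dtype={"facility_id": str})
    correlations = scale_analysis(std, dataset.utilization, dataset.facilities)

    pd.DataFrame(
        [{"y": s.y, "x": s.x, "r": s.r, "p": s.p, "n": s.n} for s in correlations]
    ).to_csv(ROOT / "scale_correlations.csv", index=False)
    pd.DataFrame(
        [
            {"y": s.y, "x": s.x, "curve_x": cx, "curve_y": cy}
            for s in correlations
            for cx, cy in zip(s.curve_x, s.curve_y)
        ]
    ).to_csv(ROOT / "scale_curves.csv", index=False)

    print("district-hospital cost-scale correlations:")
    for s in correlations:
        print(" ", render_scale_correlation(s))


if __name__ == "__main__":
    main()
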