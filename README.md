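# hospicost

Multi-site hospital costing analytics: mixed top-down/bottom-up unit costing
of specialty cost centres, bed-occupancy standardization of unit costs, and
the comparative statistics used to characterise cost heterogeneity across
provider types and city tiers — exercised end to end on a seeded synthetic
facility dataset that emulates an Indian multi-site costing sample (district,
private and tertiary hospitals across tier-1/2/3 cities).

## Who this is for

Health economists and health-technology-assessment analysts who need a
tested, reproducible implementation of facility unit costing: attributing
annual resource costs to outpatient (OP), inpatient (IP), intensive-care
(ICU) and operating-theatre (OT) cost centres, comparing unit costs across
provider types, and separating genuine cost differences from differences in
capacity utilisation and scale.

## The model

Each cost centre's annual cost splits into a fixed part *F* (salaries,
annualized capital for space, equipment and furniture) and a variable part
*V* (drugs, consumables, utilities, stationery, maintenance, overheads).
Capital purchases are annualized with the annuity factor

    A = P · r / (1 − (1 + r)^(−L))        (straight line P/L at r = 0)

with price *P*, discount rate *r* (default 0.03/yr) and useful life *L*.
The unit cost for service output *N* (visits, admissions, bed-days,
procedures) is (F + V)/N. Bed occupancy rate is

    BOR = admissions × ALOS / (beds × 365)      (may exceed 1)

and the unit cost standardized to a reference occupancy ρ* (80% or 100%) is

    c(ρ*) = F · BOR / (ρ* · N) + V / N

— variable cost per unit is invariant, the fixed component is rescaled.
Group differences are tested with the Kruskal–Wallis H (tie-corrected,
chi-square reference) and summarised with the effect size
η² = (H − k + 1)/(n − k), binned small [0.01, 0.06), moderate [0.06, 0.14),
large ≥ 0.14. Economies of scale are assessed with Pearson correlations of
unit cost against activity plus LOWESS-smoothed cost curves. INR values are
presented in USD at ₹76.21 per dollar (2020 prices).

## Worked example

```python
from hospicost import default_study_config, run_pipeline

result = run_pipeline(default_study_config(seed=1))
rows = result.comparisons
bd = rows[(rows.centre_kind == "IP") & (rows.metric == "per_bed_day")
          & (rows.grouping == "provider_type")]
print(bd[["cost_basis", "group", "n", "median", "p", "eta2", "effect_label"]]
      .round(2).to_string(index=False))
```

prints

```
  cost_basis    group   n  median   p  eta2 effect_label
  unadjusted district 202  940.20 0.0  0.18        large
  unadjusted  private  77 2218.94 0.0  0.18        large
  unadjusted tertiary  58 1248.52 0.0  0.18        large
 adjusted_80 district 202  952.29 0.0  0.45        large
 adjusted_80  private  77 1875.82 0.0  0.45        large
 adjusted_80 tertiary  58 1172.43 0.0  0.45        large
adjusted_100 district 202  844.28 0.0  0.49        large
adjusted_100  private  77 1685.09 0.0  0.49        large
adjusted_100 tertiary  58 1064.54 0.0  0.49        large
```

Read: across 337 synthetic specialties, the median unadjusted inpatient
per-bed-day cost is highest in private hospitals (₹2,219 vs ₹1,249 tertiary
and ₹940 district) — private wards run at ~50% occupancy, so their fixed
costs are spread over few bed-days. Standardizing every centre to 80%
occupancy shrinks the private premium (₹1,876 vs ₹1,172 and ₹952): much of
the observed gap is capacity utilisation, not cost structure. The same run
reports district-hospital cost–scale correlations, e.g. per-bed-day cost vs
admissions r = −0.267 (n = 202) with a convex, decreasing LOWESS curve —
the economies-of-scale signature.

## The analysis sequence

Numbered drivers under `analysis/` run the study workflow step by step and
write their tables under `results/`:

1. `01_simulate.py` — generate the synthetic facility sample and its profile.
2. `02_unit_costs.py` — annualize capital, apportion shared costs, compute
   unadjusted unit costs per centre and metric.
3. `03_standardize.py` — re-express unit costs at 80% and 100% occupancy.
4. `04_group_comparisons.py` — median/IQR, Kruskal–Wallis, η² by provider
   type and city tier, unadjusted vs adjusted.
5. `05_scale_analysis.py` — Pearson cost–scale correlations with LOWESS
   curves in district hospitals.

The same workflow is available as a CLI: `hospicost run-all --seed 1 --out
results/run` (plus `simulate`, `cost`, `standardize`, `compare`, `scale`,
`report` subcommands).

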