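# Methods

## Costing model

Every resource line item belongs to one specialty cost centre (OP, IP, ICU,
OT) or to a facility-level SHARED pool, and to one input category. The
category determines the cost class: human resources, space, equipment and
furniture are **fixed** (they do not move with output in the data year);
drugs, consumables, utilities, stationery, maintenance and overheads are
**variable**. Equipment *maintenance* is variable even though the equipment
capital is fixed. The partition is exact: each centre's annual total is
F + V with every item in exactly one class.

Capital items carry a purchase price, a useful life and an apportionment
fraction, and enter as the equivalent annual cost
P·r/(1 − (1+r)^(−L)) at discount rate r (default 0.03/yr; configurable).
Useful-life defaults: space 30 y, equipment 10 y, furniture 10 y. The
denominator is computed as −expm1(−L·log1p(r)), which is numerically stable
for rates near zero and reduces exactly to straight-line P/L at r = 0.

SHARED items are apportioned top-down across the facility's centres
proportionally to an allocation weight; the default basis is each centre's
annual service output (visits, bed-days, ICU bed-days, procedures), and a
caller-supplied weight table overrides it. Apportionment conserves totals by
construction. Operating-theatre costs are mixed: per-procedure bottom-up
resource use (quantities × prices) plus top-down fixed and variable shares;
`compute_procedure_cost` keeps the fixed/variable split so standardization
applies to procedures too.

Unit costs are (F + V)/N with N per metric: OP visits; IP admissions and
bed-days (admissions × ALOS, so per-bed-day × ALOS = per-admission exactly);
ICU analogous; OT procedures. Centres with positive cost but zero output
have no defined unit cost: they are excluded from comparisons and logged,
never imputed — medians over defined values match the descriptive approach.
All internal arithmetic is in INR at 2020 prices, full precision; rounding
happens only at presentation (INR to whole rupees; USD at ₹76.21/$ shown
with two decimals below $10, whole dollars above; p-values to four decimals
with very small values as "< 0.0005").

## Occupancy standardization

Bed occupancy rate is BOR = admissions × ALOS / (beds × days-per-year), with
days-per-year = 365 by default; values above 1 are real (over-occupancy) and
are not capped. Standardizing to target ρ* rescales the denominator to
N* = N·ρ*/BOR while variable cost scales with it and fixed cost stays
constant:

    c(ρ*) = (F·BOR/ρ* + V) / N.

Implemented exactly in this form, the identity c(BOR) = (F+V)/N holds
bitwise, V/N is invariant, and c is strictly decreasing in ρ* whenever
F > 0. OP and OT centres have no bed denominator of their own; their
utilization is scaled by the same specialty-level inpatient BOR (a theatre-
utilization measure would be a defensible alternative; the choice is
localized in `standardize_dataset` and overridable by supplying a different
occupancy). ICU metrics use the ICU's own BOR. Centres with BOR below 0.05
are standardized but flagged (`unstable_bor`), because the fixed-cost
rescaling factor BOR/ρ* becomes extreme; centres with missing occupancy are
skipped and logged.

## Synthetic facility generator

The generator emulates a multi-site sample of 27 district, 16 private and 11
tertiary hospitals (defaults) across 11 states, with 6–9 / 4–6 / 3–6
specialties per facility respectively (≈330 specialties). Per provider type
it draws beds, ALOS and IP occupancy from log-normals parameterized by
median and log-SD — medians are the published summary statistic and
log-normals make median targeting exact, while their right skew matches the
asymmetric interquartile ranges typical of facility data. Defaults: beds
27/6/52, ALOS 4.3/2.5/5.8 d, IP occupancy 0.8/0.5/0.7 and ICU occupancy
0.7/0.2/0.8 for district/private/tertiary; spreads derived from the
published IQRs (e.g. district occupancy log-SD 1.0 reproduces an IQR of
roughly 0.4–1.6 around 0.8). Mean annual OPD visits per specialty are
17,250/1,142/48,866 and OT procedures 461/269/2,389 (log-normal with
mean-preserving location, log-SD 0.8). Admissions are derived as
occupancy × beds × 365 / ALOS (rounded, min 1), so the recomputed BOR
recovers the drawn occupancy. ICU and OT centres are Bernoulli-present per
specialty at rates 45/327 and 219/327, the unit proportions of the emulated
sample.

Occupancy is truncated at a configurable ceiling (default 2.0) by
**clipping** rather than rejection-resampling: resampling a wide log-normal
below a ceiling shifts its median well under the configured target, breaking
the generator's median-calibration contract, whereas clipping above the
median leaves the median exact.

Each facility gets its own random stream keyed by (master seed, CRC-32 of
the facility id), so adding or reordering facilities never changes another
facility's draws — a subset-invariance property the tests assert.

Cost structure: per centre the fixed total is a provider-type base (set so
that, at the type's median capacity and occupancy, unadjusted unit costs sit
near the published medians — e.g. per-bed-day ≈ 819/1882/995 INR for
district/private/tertiary, per-visit ≈ 185/1251/304) scaled linearly with
beds, multiplied by a city-tier price multiplier (defaults 1.3/1.2/1.0 for
tiers 1/2/3) and log-normal noise (log-SD 0.25). The variable total is a
per-output rate times annual output with the same multipliers. Fixed totals
split 55/25/15/5% into salaries (recurrent) and space/equipment/furniture
capital blocks, with purchase prices chosen so that annuity annualization at
the generator's discount rate recovers the intended annual cost; variable
totals split 40/25/10/5/10/10% across the six variable categories. A
facility-level SHARED pool (8% of centre totals, half fixed half variable)
exercises the top-down apportionment path. Private hospitals carry a high
fixed share of bed-day cost, reflecting excess capacity at ~50% occupancy —
the mechanism by which standardization attenuates the private premium.

Economies of scale: after generation, `inject_scale_structure` multiplies
IP/ICU fixed costs by (bed-days / reference bed-days)^ε with ε < 0 (default
−0.3) where the reference is the provider type's configured median annual
bed-days. Within type, average fixed cost then falls convexly with volume —
a negative Pearson r between per-bed-day cost and admissions with curvature
a LOWESS fit captures and a straight line does not — while each type's
median cost stays at its calibration point. Anchoring the reference per
type, rather than pooling, is a deliberate choice: pooled anchoring would
distort the between-type cost levels that the group comparisons test.

### What the generator does and does not emulate

It reproduces the sample's structure (provider-type mix, tier assignment,
centre inclusion rates), the marginal medians/spreads of capacity and
utilization, realistic cost levels and decomposition, and a built-in
negative nonlinear cost–scale relationship. It does **not** model case-mix
or severity, within-state correlation, multi-year dynamics, or measurement
error in occupancy. One consequence worth noting: because the BOR used for
standardization is derived from the very admissions that generated the
costs, standardizing removes utilization noise almost exactly, so group
distributions *tighten* after adjustment and Kruskal–Wallis statistics can
grow even as median gaps shrink. In field data, occupancy is measured with
error and costs have idiosyncratic variation, so adjustment can also turn
significant differences insignificant. Directional claims about adjustment
(the private per-bed-day premium attenuates at 80% occupancy) are therefore
asserted on median gaps, not on p-value movement. Passing tests show the
pipeline's algebra and statistics are correct under these conditions; they
do not certify behaviour under case-mix confounding the generator omits.

## Statistical conventions

- Quartiles/medians: linear interpolation between order statistics (the
  common software default; published IQRs cannot adjudicate the convention).
- Kruskal–Wallis: tie correction always applied; p from the chi-square
  approximation with k−1 df. The degenerate all-identical case returns
  H = 0, p = 1 (the exchangeable identity). Exact enumeration appears only
  in tests, as an independent oracle at n ≤ 8.
- η² = (H − k + 1)/(n − k); negative values (H below its null expectation)
  are reported as-is and labelled `below_small`, as are values < 0.01.
- Correlation: product-moment Pearson on raw values (matching r-on-scatter
  usage), with Spearman exposed as an option.
- LOWESS: tricube-weighted local linear fit (statsmodels), span 2/3 and 3
  robustness iterations by default; duplicate x positions are collapsed to
  keep curve x strictly increasing.
- No multiple-testing adjustment anywhere — a deliberate fidelity choice to
  the descriptive reporting style; pairwise contrasts use two-group
  Kruskal–Wallis.

## Problem sizes and numerical tolerances

The analysis drivers run at the study-sized default (54 facilities, ≈330
specialties; seconds). Median-recovery checks use ≈2,000 centres per
provider type, where the sampling error of a log-normal median (≈2–3%) sits
well inside the ±10% recovery band; scale analysis uses ≈300 district IP
centres. Type-I calibration uses 3 groups × 30 observations over 1,000
replicates, large enough per group for the chi-square reference to be
accurate. Convexity of the LOWESS cost curve is detected by the chord test:
the maximum gap between the curve and the straight line joining its
endpoints, as a fraction of the curve's range (linear data give ≈0; the
generated cost curves give ≈0.7). Standardization identities hold exactly in
floating point by construction; apportionment conservation holds to ~1e−7
INR on 1e8-scale items; monetary aggregation error is bounded far below
0.01 INR.

## Known limitations

- Single-pass proportional allocation of shared costs; no multi-tier
  step-down cascade.
- No patient-level costing, case-mix adjustment, or efficiency frontier
  estimation (descriptive analytics only).
- Tier effects enter only through price multipliers; tier-specific capacity
  profiles are not separately calibrated (the available tier-level summary
  data were internally inconsistent, so provider-type blocks carry the
  calibration).
- The USD presentation rule (two decimals under $10, whole dollars above)
  is a fixed convention; published tables sometimes mix precisions.
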