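# Methods

## The tier system

The 2014 Health Canada Surveillance Tool (HCST) grades every food in the four
main food groups of Eating Well with Canada's Food Guide (EWCFG) — Vegetables
& Fruits, Grain Products, Milk & Alternatives, Meat & Alternatives — into
four ordinal tiers from its nutrient content *per reference amount* (RA), the
regulated quantity of the food usually eaten at one sitting.

Thresholds per RA (all configurable; defaults are the published constants):

| nutrient      | lower   | upper   |
|---------------|---------|---------|
| total fat     | 3 g     | 10 g    |
| sugars        | 6 g     | 19 g    |
| sodium        | 140 mg  | 360 mg  |
| saturated fat | —       | 2 g     |

"Exceed" is strict everywhere: a food at exactly 3 g fat / 6 g sugars /
140 mg sodium per RA does **not** exceed the lower thresholds and stays
eligible for Tier 1.

Step 1 decision table, with `L` = number of lower exceedances (fat, sugars,
sodium), `U3` = number of upper exceedances among fat/sugars/sodium and `S`
= saturated-fat upper exceedance:

* **Vegetables & Fruits, Grain Products** (`U = U3 + S`):
  `U >= 2` → Tier 4; `U = 1` → Tier 3; otherwise `L = 3` → Tier 3,
  `1 <= L <= 2` → Tier 2, `L = 0` → Tier 1.
* **Milk & Alternatives, Meat & Alternatives** (saturated fat never counts
  toward Tier 4, reflecting its intrinsic presence in these groups):
  `U3 >= 2` → Tier 4; `U3 = 1` → Tier 3; `U3 = 0` and `S` → Tier 3;
  otherwise the same `L` ladder.

One reading ambiguity is resolved here and is worth stating: for milk/meat
groups, "only exceeds the upper saturated-fat threshold" is read as *only
among the upper thresholds* — lower exceedances do not block the Tier-3
saturated-fat branch. Under this reading the decision table partitions the
profile space (exactly one tier per profile) and is monotone: raising any
single nutrient can never lower the tier. Both properties are enforced by
property tests and an exhaustive boundary-grid comparison against an
independently coded brute-force oracle.

Step 2 applies guidance adjustments declared in configuration, in order,
first match wins. Only one rule is published explicitly and only that rule
ships enabled: whole grains whose fat comes from naturally occurring oils
move from Tier 2 back to Tier 1 when the fat lower threshold is their
trigger. The rule schema (flag, from-tier, to-tier, required lower
exceedances) accepts further rules without code changes.

Foods outside the four main groups are not tiered but categorized: high
fat/sugar foods, saturated/trans fats and oils, high-calorie beverages
(>= 40 kcal/100 g), low-calorie beverages (< 40 kcal/100 g), alcoholic
beverages, meal replacements, supplements, and uncategorized items. Water
and unsaturated (healthy vegetable) oils are *recommended* "other" foods:
they are excluded from the non-recommended energy aggregate below.

### The 21-subgroup taxonomy

The four main groups subdivide into 21 subgroups. The authoritative list
lives in Health Canada's technical documentation; the taxonomy shipped in
`hcst/data/default_config.yaml` is a faithful-as-possible reconstruction
from the subgroups named in the surveillance literature (potatoes, fruit
juice, whole grains, fluid milk & fortified soy beverages, legumes, eggs,
beef/game/organ meat, poultry, processed meats, ...). The rule engine keys
on subgroup *attributes*, not names, so the list can be amended in
configuration without touching code.

## Recall metrics

Per respondent-day the package computes:

* **Servings** — consumed grams / grams per EWCFG serving, fractional,
  unrounded. Tier 4 foods are tallied in the "Tiers 1-4" accounting row but
  provide no serving toward the recommendation ("Tiers 1-3").
* **Energy by tier/category** — conserved exactly: the kcal tallied under
  Tiers 1-4 plus every other-food category sum to reported energy intake
  (EI) within 0.1 kcal, asserted structurally.
* **Percent energy from non-recommended foods** — 100 × (Tier 4 energy +
  non-recommended other energy) / EI, with water and unsaturated oils
  excluded from the numerator. This is the compliance metric.
* **Nutrient density** — amount per 1000 kcal; macronutrients additionally
  as percent of energy using Atwater factors 9/4/4/7 kcal/g for
  fat/carbohydrate/protein/alcohol (added sugars at 4 kcal/g). The source
  analysis does not state its factors; these standard values are a package
  choice. Alcohol energy stays in the denominator for all ages.
* **Glycemic index/load** — item GL = GI × carbohydrate g / 100; daily GL is
  the sum; dietary GI is the carbohydrate-weighted mean over carb-bearing
  items. GI assignment uses a three-level hierarchy replacing the full
  published food-matching protocol (which needs external tables): food-level
  value if present, else the configured subgroup median, else a global
  default of 55 with a warning.
* **Energy density** — kcal/g over foods only, excluding all beverages;
  undefined (missing, logged) for an all-beverage day.
* **BMI** — weight (kg) / height (m)².

## Energy-misreporting screen

Estimated energy requirement (EER) comes from the IOM factorial equations
(DRI 2005): for ages 3-18,
`EER = intercept + age_coef·age + PA·(weight_coef·weight + height_coef·height) + growth`,
with sex-specific coefficients and PA multipliers (sedentary = 1.00 by
construction), and a PAL-free young-child form (`89·weight − 100 + 20`) for
ages 2-3. The coefficient table ships in configuration with this provenance
note; loading refuses to run if any sex/age band is uncovered rather than
guessing. The survey that motivated this pipeline collected no activity
data under age 6, so for ages 3-6 a missing PAL falls back to sedentary (a
conservative, documented default); from age 6 a missing PAL makes the
respondent ineligible, as does missing weight or height.

The EI/EER ratio is screened against age-banded cutoffs taken as given
constants (their derivation from ±1 SD intervals is not reproducible from
the published description): under < 74 %, over > 135 % below age 12;
under < 70 %, over > 142 % from age 12. Inequalities are strict, so a ratio
exactly at a cutoff is plausible. The band switch sits at exactly 12.0
years.

## Compliance stratification

Respondents are ranked on percent energy from Tier 4 + non-recommended
foods within two strata split at age 12 (children / adolescents), mirroring
the reporting stratification. Quartile cutpoints are survey-weighted by
default (all downstream analyses are weighted; whether the original
cutpoints were weighted is not stated, so an unweighted mode is provided).
The weighted quantile is defined to be *weight-replication consistent*: a
record of weight w behaves exactly like w unit-weight copies, and with
equal weights it reduces to the ordinary linear-interpolation sample
quantile. Ties at a cutpoint go to the lower quartile (deterministic and
order-independent; a degenerate all-equal stratum lands entirely in Q1).
Q1 = complier, Q2-Q3 = intermediate, Q4 = non-complier.

## Survey statistics

Point estimates are weighted means under the main survey weight. Variance
comes from bootstrap replicate weights in the balanced-repeated-replication
style: SEM = sqrt((1/B) Σ_b (mean_b − mean)²) over the B replicate-weight
columns, with an optional Fay adjustment factor (default 0; the design
effect factors of the original survey are not published). The trend test
across quartiles is ordinary weighted least squares of the outcome on the
quartile index (1-4 linear score) plus covariates — age, sex and
misreporting status — with a two-sided p-value on the slope. This is a
deliberate simplification of full survey-design regression (SAS
SURVEYREG/SURVEYLOGISTIC are out of scope); a weighted logistic analogue
reports per-quartile-step and Q4-vs-Q1 odds ratios for binary outcomes.
Type-I error of the trend test is verified at the nominal 5 % level by null
simulation, and slope recovery at the nominal 2-SE coverage.

## Synthetic data: what it emulates, and what it does not

The generator stands in for restricted-access national survey microdata; no
real dietary values are reproduced. It emulates the *structure* the
analysis assumes:

* a food table in which every main subgroup spans all four tiers — profiles
  are drawn inside each tier's threshold window, then verified by the
  classifier (construction failure is an error, not a silent skip);
* macronutrient-consistent energies (item kcal = Atwater energy of its
  macros), so percent-of-energy accounting closes by construction;
* tier-graded food quality: lower tiers are generated fibre-, protein- and
  micronutrient-richer, higher tiers more energy-dense, saltier, higher in
  added sugars and GI;
* a cohort of 2000 respondents aged 2-18 (a desk-scale stand-in for the
  ~13,700 of the motivating survey), both sexes, with simple linear
  growth-curve anthropometry, ~3 % missing anthropometry, lognormal survey
  weights and B = 50 bootstrap replicate-weight columns (multinomial
  resampling);
* three consumption archetypes — complier / intermediate / non-complier in
  proportions 25/50/25 — whose target share of energy from Tier 4 +
  non-recommended foods is drawn from N(0.07, 0.03), N(0.30, 0.06) and
  N(0.60, 0.06) respectively, with item amounts rescaled to hit the target;
  population mean lands near one-third of energy, consistent with the
  order of magnitude surveillance reports for this age range;
* a misreporting mixture: 10 % report at 0.6 × EER, 10 % at 1.6 × EER, the
  rest at an archetype-specific centre (0.95 / 1.00 / 1.05 × EER) with
  lognormal noise (σ = 0.08) that keeps plausible reporters inside the
  plausibility band with high probability.

Not emulated: real food-composition marginals, day-to-day intake variation,
intra-household correlation, the survey's multi-stage design (weights are
i.i.d. lognormal), seasonal or regional effects. Passing recovery tests
therefore demonstrates that the pipeline detects structure that is truly
present at realistic sizes and noise levels — not that the biological
findings themselves are reproduced.

## Numerical choices

* Tier windows in the generator keep a ~5 % margin away from every
  threshold so constructed tiers are unambiguous under float rounding.
* Energy conservation is asserted at 0.1 kcal absolute per respondent.
* The replicate-SEM snaps to exactly zero when it is below 1e-12 relative
  to the mean (identical replicate columns up to summation order).
* The trend test detects zero residual variance (exact fits) and returns
  p = 1 for an exactly flat outcome, p = 0 for an exact non-zero trend.
* All randomness flows from `numpy.random.default_rng` seeded from a single
  integer; food-table and cohort generation use separate child streams so
  `generate_foods(spec, seed)` is reproducible inside `generate_cohort`.
* Problem sizes: the default cohort is n = 2000 with 50 replicate weights;
  calibration checks use 500 null simulations (n = 200) and 200 recovery
  simulations (n = 2000).

## Known limitations

* The step-2 adjustment list contains only the one published rule; the full
  set exists only in Health Canada's technical annex.
* The weighted trend test is not a design-based variance estimator; with
  strongly informative weights its p-values are approximate.
* The GI hierarchy's subgroup medians are configuration values typical of
  published GI tables, not a validated matching of any food database.
* Quartile cutpoints from the restricted-access survey (e.g. the published
  22.29 / 33.83 / 47.48 % energy cutpoints for children) are reproduced in
  *form* only; the synthetic cohort produces its own cutpoints.
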