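# Methods

## Indicators

For each child aged 6–23 completed months, seven binary indicators
record consumption of the complementary-food groups in the previous
24 h: (1) grains, roots and tubers; (2) legumes and nuts; (3) dairy
products; (4) flesh foods (meat, fish, poultry, organ meats); (5) eggs;
(6) provitamin-A-rich fruits and vegetables; (7) other fruits and
vegetables. With `score7` the count of groups consumed and `breastfed`
the breastmilk indicator for the same window,

- `MDD-7 = 1{score7 ≥ 4}` — the earlier definition, breastmilk excluded;
- `score8 = score7 + breastfed`, `MDD-8 = 1{score8 ≥ 5}` — the updated
  definition with breastmilk as an eighth group.

Both thresholds are inclusive and deliberately not configurable: the
definitional change is the object of study, and configurable cut-offs
invite silent indicator drift. Two consequences are used as exact test
invariants throughout: MDD-8 implies MDD-7 for every possible diet
pattern, and `mean(score8) − mean(score7)` equals breastfed prevalence
under any common weighting.

## Design-based estimation

Point estimates are Hajek ratio estimators `p̂ = Σwᵢyᵢ / Σwᵢ`. Variances
use first-stage Taylor linearization: with linearized variate
`zᵢ = wᵢ(yᵢ − p̂)/Σw`, PSU totals `z_hc`, and `n_h` PSUs in stratum `h`,

    Var(p̂) = Σ_h  n_h/(n_h−1) Σ_c (z_hc − z̄_h)².

With one stratum, equal weights and every record its own PSU this
reduces exactly to the SRS form `p(1−p)/(n−1)`, which the tests assert.
Subgroups (the 6–11 and 12–23 month bands) are estimated as domains:
out-of-domain records keep their PSUs in the computation with zeroed
variate, so domain SEs reflect the random band sizes.

Numerical and convention choices:

- 95% CIs for proportions are logit-transformed by default (respects
  [0, 1]; the common convention of survey software for prevalence);
  Wald is available by flag. Means use Wald CIs.
- The normal quantile 1.959964 is used rather than a t quantile; PSU
  counts in the target surveys (hundreds) make the difference invisible
  at reported precision.
- Degenerate outcomes (constant y, or p̂ ∈ {0, 1} under the logit
  method) yield SE 0 and a CI collapsed to the point.
- Strata with a single PSU raise an error by default; an explicit
  `singleton="centered"` option centres the lone PSU total at the grand
  mean instead. Silent fixes hide design mis-specification.
- CI overlap is evaluated on closed intervals: touching endpoints count
  as overlap.
- Estimates are invariant to rescaling all weights by a constant, so
  relative weights suffice.

Out of scope: replicate-weight (BRR/bootstrap) variance,
finite-population corrections, and variance contributions beyond the
first-stage PSU approximation.

## Lowess age curves

Age patterns are smoothed with a pinned Cleveland-style variant: at
each evaluation age x₀ the `ceil(bandwidth·n)` nearest observations by
|age − x₀| (boundary ties all included) get tricube weights
`(1 − (d/d_max)³)³` on distance normalized by the span radius, and a
weighted least-squares line is evaluated at x₀. No robustness
iterations. Binary outcomes are smoothed directly as 0/1 microdata, the
grid is the set of distinct observed ages (monthly data granularity),
and — unlike every other estimate in the package — the smoother ignores
design weights, matching the convention for these descriptive curves.
The exact lowess variant behind published figures of this kind is
rarely recoverable from text; pinning one variant makes outputs
reproducible, and the choice is validated by closed-form properties
(exact on constant and linear data) plus an independent step-by-step
oracle rather than by matching any particular software. Degenerate
neighbourhoods (all span weight at one age) fall back to the local
weighted mean. Default bandwidth 0.7.

## Synthetic cohort generator

The generator emulates the features of DHS-style surveys that matter to
the estimators, with all behaviour governed by a `ScenarioConfig`:

- **Design**: `n_clusters` PSUs allocated round-robin over `n_strata`
  strata (≥2 per stratum enforced); cluster sizes Poisson around
  `children_per_cluster` (min 1), exercising unequal-cluster variance;
  weights gamma with mean 1 and CV `weight_dispersion` — positive and
  right-skewed like real design weights, independent of outcomes
  (non-informative weighting).
- **Ages**: uniform over 6..23 months by default, configurable.
- **Breastfeeding**: `logit P(breastfed | age) = a + b·age`; negative
  `b` reproduces the decline of continued breastfeeding with age.
- **Food groups**: `logit P(group g | age) = c_g + s·age + u`, with a
  shared per-child latent shift `u ~ N(0, σ)` inducing the positive
  inter-group correlation of real diets while keeping the σ = 0 case
  exactly enumerable.

`true_indicator_values` returns the population values the scenario
implies. With σ = 0 it is exact: per age, the 7-group count follows a
Poisson-binomial law computed by convolution (equivalent to summing all
2⁷ patterns), combined with the two breastfeeding states and the age
distribution. With σ > 0 it is a seeded Monte-Carlo estimate (default
10⁶ children). The two routes agree within sampling error, which is
itself a test.

Two presets are calibrated so that scenario truth matches published
national moments from Eastern/Southern African surveys:
`high-bf-low-diversity` (second-year breastfeeding ≈ 79.3%, mean
diversity ≈ 1.8 groups) and `low-bf-high-diversity` (≈ 34.7%, ≈ 3.5).
Calibration solved the breastfeeding intercept/slope against the two
age-band targets and a common food-group intercept shift against the
mean-diversity target by Gauss–Hermite integration over the latent
shift (σ = 0.9, a realistic diet correlation); the per-group intercept
offsets encode typical relative frequencies (staple grains most common,
eggs rarest). Default preset size is ~4,000 children (200 clusters of
~20 in 10 strata, weight CV 0.5), comparable to the surveys emulated.

What the generator does **not** emulate: joint dependence of
breastfeeding and food groups given age (no such joint model is
published for these data), household structure (youngest-child
selection is assumed already applied), non-response, seasonality, and
any specific country's full design. Passing tests therefore demonstrate
correctness of scoring, estimation and smoothing under a realistic but
idealized design — not robustness to informative weighting or to
questionnaire-level measurement error.

## Ingest conventions

Delimited text (comma default, tab accepted, UTF-8, header required)
via a YAML column mapping. Item columns OR-aggregate into groups; a
value is truthy after lowercasing/stripping iff it is in the configured
truthy set (default `{"1", "yes"}`). A missing single diet item counts
as "not consumed"; a record is dropped only when every diet item,
breastmilk included, is missing — the standard large-survey convention,
with all exclusions (age ineligibility, non-positive weights,
all-missing diets, unparseable values) counted in an ingest report.
Ages outside 6–23 completed months are excluded as ineligible.
Youngest-child de-duplication keeps the minimum age per household, ties
broken by smallest child id. Native DHS binary formats are not parsed;
an example DHS-style mapping ships in `examples/` for documentation.

## Problem sizes in tests

The test suite verifies convergence properties at the scale where the
relevant sampling error is decisive: logistic-curve recovery on ~50,000
children, enumeration-vs-Monte-Carlo agreement at 10⁶ draws, parameter
recovery on ~4,000-child preset cohorts, and CI calibration over 200
replicates (coverage asserted within [90%, 98%]). Smoothed-curve shape
properties use ~20,000-child cohorts, where the monthly curves are
stable to well under a percentage point.
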