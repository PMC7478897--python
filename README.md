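# mddkit

Minimum dietary diversity (MDD) is a population-level indicator of diet
quality for children aged 6–23 months, collected in large household
surveys such as the DHS. Its definition was updated from **MDD-7**
(consumed ≥4 of 7 complementary-food groups in the previous 24 h) to
**MDD-8** (consumed ≥5 of 8 groups, with breastmilk counted as the
eighth group). Because every child meeting MDD-8 also meets MDD-7, the
updated indicator is mechanically lower, and the size of the drop
depends on a country's breastfeeding and diet patterns — a real problem
for nutrition programme monitoring, where a definitional change can
masquerade as a regression in progress.

`mddkit` is a tested pipeline for computing and comparing the two
definitions from child-level survey microdata, aimed at nutrition
epidemiologists and survey analysts:

- **Scoring** — per-child group counts `score7 = Σ g_i` (the 7 food
  groups), `score8 = score7 + breastfed`, and the classifications
  `MDD-7 = 1{score7 ≥ 4}`, `MDD-8 = 1{score8 ≥ 5}`.
- **Design-based estimation** — weighted prevalences `p̂ = Σwᵢyᵢ/Σwᵢ`
  and means with Taylor-linearized standard errors for stratified
  cluster (PSU) designs, logit-transformed or Wald 95% CIs, age-band
  domain estimation, and CI-overlap checks.
- **Age smoothing** — Cleveland-style lowess (tricube nearest-neighbour
  local lines, bandwidth 0.7, no robustness iterations) of the
  breastfeeding, MDD-7 and MDD-8 indicators across 6–23 months.
- **Country comparison** — publication-style per-survey rows and the
  arithmetic MDD-8 − MDD-7 difference in percentage points, ranked
  across surveys.
- **Synthetic cohorts** — a DHS-like generator (clusters in strata,
  gamma weights, logistic age curves for breastfeeding and food-group
  consumption, a latent child-level shift correlating food groups) with
  exactly computable population truth, so every stage is testable
  without restricted survey microdata.
- **Ingest** — delimited-text microdata via declarative column
  mappings, with OR-aggregation of item columns into food groups and
  youngest-child-per-household de-duplication.

## Worked example

```python
from mddkit import compare_country, generate_cohort, preset_scenarios

cohort = generate_cohort(preset_scenarios()["low-bf-high-diversity"], seed=11)
row = compare_country(cohort, label="low-bf-high-diversity")
print(row.mdd7.estimate, row.mdd8.estimate, row.difference_pp)
```

Running `python examples/04_compare_definitions.py` prints:

```
published 14-survey worked example:
  largest gap:  South Africa (-8.9 pp)
  smallest gap: Ethiopia (-1.4 pp)
  surveys with |gap| > 5 pp: 3
  surveys whose MDD-7/MDD-8 CIs do not overlap: ['South Africa', 'Tanzania', 'Uganda', 'Zimbabwe']

synthetic South-Africa-like survey, full pipeline:
  MDD-7 48.7% (46.9, 50.5), MDD-8 37.8% (36.1, 39.5)
  difference: -11.0 pp, CIs non-overlapping: True
```

The first block recomputes, from published national estimates of 14
Eastern/Southern African DHS surveys, how far the indicator change
moves each country (South Africa, with low second-year breastfeeding
and high diversity, drops 8.9 percentage points; Ethiopia only 1.4).
The second block runs the whole pipeline — simulation, scoring,
design-weighted estimation — on a synthetic survey calibrated to
South-Africa-like moments: the 95% CIs of the two definitions do not
overlap, reproducing the pattern seen in the real data.

The other scripts in `examples/` demonstrate scoring, design-based
estimation with age-band domains, and the lowess age curves (the MDD-7
vs MDD-8 gap widens with age as children are weaned). A thin CLI mirrors
the library: `mdd simulate | ingest | score | estimate | curves |
compare` (see `mdd --help`).

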