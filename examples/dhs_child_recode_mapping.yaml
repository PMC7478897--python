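# Example column mapping for a DHS-style child recode exported to CSV.
#
# Documentation-only preset: DHS diet-item variables (the v414* series)
# differ across survey rounds and countries, so ALWAYS check the item
# list against the survey's questionnaire before use.  Proprietary DHS
# file formats are not parsed; export the recode to delimited text first.
cluster: v001        # cluster number (PSU)
stratum: v023        # sample stratum
weight: v005         # sample weight (rescaling does not affect estimates)
age: age_months      # derived child age in completed months
breastmilk: bf_prev_day   # breastmilk in previous 24 h (derive from m4 == 95)
household_id: v002   # household number, for youngest-child de-duplication
groups:
  grains_roots_tubers: [v414e, v414f]        # bread/grains; tubers
  legumes_nuts: [v414o]
  dairy: [v411, v411a, v414v, v414p]         # milk; formula; yogurt; cheese
  flesh_foods: [v414h, v414m, v414n]         # meat; organ meat; fish
  eggs: [v414g]
  vita_fruits_vegetables: [v414i, v414j, v414k]  # vit-A veg; leafy greens; vit-A fruit
  other_fruits_vegetables: [v414l]
truthy: ["1", "yes"]
missing_codes: ["", ".", "8", "9", "na"]
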