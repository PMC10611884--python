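# Default configuration of the threshold-derivation pipeline.
# The assessment factors and the reliability rubric are editable
# reconstructions of the cited national derivation guidance, not
# reprinted values.

# species count at and above which the Burr III distribution is used
# ("auto" policy); below it the two-parameter log-logistic is fitted
auto_burr_min_n: 8

# per-species aggregation of accepted toxicity values
species_aggregation: geometric_mean

# divisor applied to the single lowest value, keyed to its endpoint class,
# when the minimum-data rule (>= 5 species from >= 4 taxonomic groups) fails
assessment_factors:
  chronic: 10
  chronic_estimated: 20
  converted_acute: 100

# most sensitive group of organisms by mode of action, used when the caller
# declares the per-species data bimodal
sensitive_groups:
  herbicide: [phototroph]
  insecticide: [arthropod]
  nematicide: [arthropod, nematode]
  fungicide: [fungus]

# monotone reliability rubric: the three component scores are summed and the
# total mapped onto the class cuts (first cut whose threshold is met)
reliability_rubric:
  size_tiers:            # [min species, min taxonomic groups, score]
    - [15, 5, 3]
    - [8, 4, 2]
    - [5, 4, 1]
  endpoint_scores:
    all_chronic: 2
    mixed: 1
    all_converted_acute: 0
  fit_scores:
    good: 2
    acceptable: 1
    poor: 0
  class_cuts:            # [minimum total score, class]
    - [7, very_high]
    - [5, high]
    - [3, moderate]
    - [1, low]
    - [0, very_low]
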