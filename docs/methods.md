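# Methods

This note records the model implemented by `pdst`, the defaults it ships,
the numerical choices behind them, and what the bundled data and synthetic
generators do and do not represent.

## The risk model

The aquatic-risk score for one formulation of an active ingredient is

    risk = effect × mobility

with

    effect   = A / (T × 10⁶)                       [ML/ha]
    mobility = t½_soil × t½_water × p              [d² × proportion]
    p        = clamp((−10.076 log₁₀ K_OC + 39.123) / 100, floor, 1)

* *A* — application rate in µmol AI/ha: product label rate × AI fraction
  (× density for volumetric labels), divided by the release interval in
  years for slow-release formulations (default interval 4, stored per
  record), converted by 10⁹/M with M the molar mass in g/mol. The `max`
  label bound is the default; `min` and `mean` (arithmetic midpoint of the
  label bounds) are available, and only the ranking — not the absolute
  value — is intended to carry meaning.
* *T* — the threshold in µmol/L (converted to µmol/ML inside the effect
  quotient). Thresholds are jurisdictional guideline values where they
  exist, otherwise derived in-package (below).
* *p* — proportion of the applied ingredient transported in runoff,
  predicted from K_OC alone by a linear fit to rainfall-simulation field
  trials on a poorly drained hydrosol. The logarithm is base 10, matching
  the log K_OC / log K_OW convention used throughout. The line is negative
  above log₁₀ K_OC ≈ 3.883; the default clamp floor is 0, configurable
  (`--floor`) because reference tables carry a small positive mobility
  (~0.01) for strongly sorbed compounds rather than zero.
* Both the raw product and the /100 "reported" scale are always emitted;
  display rounding is 2 significant figures (round-half-even), with full
  precision retained internally.

The score is homogeneous of degree 1 in application rate, so band or spot
spraying a fraction *f* of the field scales risk by exactly *f*. Tank-mix
totals are plain sums of component risks and are labelled indicative: they
assume additivity and ignore the joint-toxicity question entirely.

Dominance comparison: formulation *a* is preferred outright when it is at or
below *b* on both axes with at least one strict inequality; otherwise the
risk product breaks the trade-off. Whenever *a* dominates, its risk product
is necessarily no larger than *b*'s, so the two rules never disagree.

## Threshold derivation

1. **Per-species aggregation.** One value per species: the geometric mean of
   its quality-accepted records (configurable to the minimum). Quality
   screening itself is out of scope; records arrive with an accepted flag.
2. **Bimodality.** Whether the data are bimodal is declared by the caller
   from the mode of action (phototrophs vs the rest for herbicides,
   arthropods for insecticides, …), mirroring expert practice; an advisory
   gap statistic on log values is available but never acts automatically.
   For bimodal data only the most sensitive group is retained.
3. **Minimum-data rule.** The SSD route requires ≥ 5 species from ≥ 4
   taxonomic groups; otherwise the assessment-factor route is taken.
4. **SSD fit.** Maximum likelihood on the positive-value scale:
   log-logistic (α scale, β shape; equivalently a logistic on log values)
   for n < 8 species, Burr III (b, c, k; F(x) = (1 + (x/b)^−c)^−k) for
   n ≥ 8. The Burr III likelihood is maximised by Nelder–Mead over
   (ln b, ln c, ln k) from multiple starts anchored at the nested
   log-logistic solution (k = 1); an optimiser failure falls back to the
   log-logistic with the convergence flag cleared. This policy is an
   approximation of the behaviour of the standard national derivation
   software, whose internals are not public. Quantiles are evaluated in log
   space so extreme shape parameters (flat likelihood ridges at small n)
   remain finite, and PC99 ≤ PC95 ≤ PC90 ≤ PC80 holds by construction.
5. **Percentile policy.** PC95 by default; PC99 when log K_OW ≥ 4
   (boundary included), flagging potential biomagnifiers. AF-derived
   thresholds carry no percentile.
6. **Assessment factors.** Lowest value ÷ factor, keyed to the endpoint
   class of that lowest value: chronic 10, chronic-estimated 20,
   converted-acute 100. The cited guidance does not print its factors;
   these defaults are an explicit reconstruction and ship in
   `pdst/data/derivation_config.yaml`.
7. **Reliability.** A monotone score rubric over data volume (species ×
   groups), endpoint mix, and fit quality (graded by a one-sample KS test:
   p ≥ 0.5 good, ≥ 0.05 acceptable, else poor), mapped to
   very_low … very_high. AF thresholds are always "unknown". The rubric is
   likewise a reconstruction of cited-but-unprinted criteria and is fully
   configurable.

No bootstrap confidence intervals are computed by default; the tool consumes
point thresholds only.

## Calibration statistics

* **Spearman rank correlation** uses average ranks and a two-sided p-value:
  exact enumeration of all n! permutations for n ≤ 9, the t-approximation
  with n − 2 degrees of freedom above that. Whether published trial p-values
  were exact or approximate is not stated, so both are offered.
* **Runoff-loss regression** is ordinary least squares of percent loss on
  log₁₀ K_OC per soil type; outlier exclusion (e.g. a charged compound on
  sandy soil) is an explicit drop-list argument, never automatic.
* **K_OC reconciliation** reports the symmetric fold difference between
  experimental and modelled values; the resolved K_OC always prefers the
  experimental number when present (the modelled estimator is known to fail
  for divalent cations by roughly three orders of magnitude).
* **Rate sensitivity** recomputes effect rankings under the max/min/mean
  label bounds and reports the pairwise Spearman matrix.

## Bundled reference dataset

`pdst/data/` carries a 47-ingredient, 48-formulation table for sugar cane
and its rotation crops. Thresholds (value, type, method, percentile,
reliability) are the published ones. The original label rates and the exact
half-life table live in supplementary material that is not bundled, so:

* application rates are **back-computed** from the published effect values,
  the thresholds and real molar masses (they agree with the rates the main
  text does print, e.g. 4.72 vs 4.75 kg AI/ha for MSMA and 0.0070 kg/ha for
  metsulfuron-methyl, but are reconstructions);
* K_OC and soil half-lives are realistic database-style values, and the
  water half-life is **back-solved** so the mobility measure reproduces the
  published column exactly;
* for the six strongly sorbed compounds (log K_OC > 4) whose runoff
  proportion clamps to zero, the published mobility of ≈ 0.01 is stored as
  a per-record override (`mobility_given`) rather than computed;
* minimum rates are plausible fractions of the maxima; the published
  ranking-stability bound across rate bounds (ρ ≥ 0.95) is a property of
  the original labels and is reported, not asserted, for this
  reconstruction.

One published row (a triazine herbicide) could not be recovered unambiguously
from the source table's formatting; its stored values satisfy the product
identity and the published ordering of the photosystem-II herbicides and are
marked reconstructed like the rest.

## Synthetic generators

* `generate_fixture_table` draws property tables log-uniformly over ranges
  spanning the bundled data (K_OC 1–10⁶ L/kg, DT50 0.1–10⁴ d, thresholds
  10⁻⁷–10 µmol/L, rates 0.005–5 kg/ha, class frequencies 32:9:5:1). It
  produces structurally valid tables for property tests; it does not model
  the correlations real chemistry induces (e.g. between K_OW and K_OC), so
  passing tests demonstrate engine correctness, not realism of any
  particular risk value.
* `generate_toxicity_dataset` draws per-species sensitivities log-normally
  (default µ = −1, σ = 0.5 log₁₀ units — a typical SSD spread). The
  Monte-Carlo PC95 recovery test draws at σ = 0.3: at n = 32 species the
  irreducible sampling noise of even a correctly specified
  maximum-likelihood oracle is ~13.6 % median relative error at that
  spread (and ~23 % at σ = 0.5), so σ = 0.3 is the condition under which a
  15 % bound distinguishes estimator overhead from sampling noise. Real
  toxicity data add inter-laboratory variance, censoring and taxonomic
  clustering that the generator does not emulate.
* `generate_runoff_trials` places trials on (or Gaussian-noisily around)
  the runoff line with K_OC log-uniform over the un-clamped range,
  truncating losses at zero.

## Numerical choices and degenerate inputs

* SSD fitting refuses fewer than two distinct values; empty accepted sets,
  empty bimodal subsets and empty tank mixes raise typed errors rather than
  returning sentinels.
* Ranking uses average ranks for ties (required by the Spearman machinery);
  formulations of the same ingredient rank separately.
* Significant-figure rounding is round-half-even, matching the binary
  rounding used by the supporting numerical libraries.
* CSV I/O is comma-separated UTF-8 with a header row and "." decimals;
  round trips preserve full double precision (values are written via
  `repr`).
* CLI exit codes: 0 success, 2 validation/schema/integrity, 3 I/O.

## Limitations

* Only the surface-runoff pathway is scored: no leaching, erosion,
  spray-drift, or in-stream fate, and no site specificity (soil, slope,
  rainfall). The score ranks; it does not predict concentrations.
* A single K_OC value stands in for sorption; pH effects on ionisable
  compounds (pK_a is stored but unused) and sediment-phase transport of
  strongly sorbed cations are outside the model.
* Tank-mix sums ignore interaction; the output is labelled indicative.
* Small differences in risk between compounds should be read cautiously;
  order-of-magnitude differences are the signal the tool is designed to
  surface.
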