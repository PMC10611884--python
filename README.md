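# pdst — a Pesticide Decision Support Tool for aquatic risk

`pdst` ranks pesticide active ingredients (PAIs) by the risk they pose to
freshwater ecosystems receiving agricultural runoff. It is aimed at the
decision its users — farmers, agronomists, resellers, and the scientists
advising them — actually face: *of the products registered for my crop, which
active ingredient is least likely to reach a waterway and cause harm?* The
tool deliberately uses only readily available inputs (label application
rates, K_OC, soil and water half-lives, and water-quality thresholds), no
site-specific hydrology, and no weighting scheme, so that the resulting score
is simple, transparent, and comparable across compounds.

## The score

For each active ingredient, two measures are combined:

**Measure of effect** — an exposure-to-toxicity surrogate:

    effect = A / T

where *A* is the maximum permitted application rate in µmol AI/ha and *T* is
the ecotoxicity threshold (a default guideline value, DGV, or an ecotoxicity
threshold value, ETV) expressed in µmol/ML (µmol/L × 10⁶). The units, ML of
water per hectare, read as the dilution volume needed to bring the applied
dose down to the threshold.

**Measure of mobility and persistence** — how much reaches water, and how
long it lasts:

    mobility = t½(soil) × t½(water) × p,
    p = clamp[ (−10.076 · log₁₀ K_OC + 39.123) / 100 ]

where *p* is the proportion of the applied ingredient predicted to be lost to
runoff, from a linear regression of field-trial runoff losses on log₁₀ K_OC
(clamped to [0, 1]; the line crosses zero near log₁₀ K_OC ≈ 3.9).

**Aquatic risk** is their product, `risk = effect × mobility`; reference
tables print `risk / 100`. It is a unitless ranking score — a likelihood
surrogate, not a predicted environmental concentration.

The thresholds themselves are derived in-package where no guideline value
exists: one chronic toxicity value per species (geometric mean), a species
sensitivity distribution (log-logistic for small datasets, Burr III for
n ≥ 8, by maximum likelihood) whose 5th percentile (PC95) — or 1st percentile
(PC99) for potential biomagnifiers with log K_OW ≥ 4 — becomes the ETV; when
fewer than five species spanning four taxonomic groups are available, the
lowest value divided by an assessment factor is used instead.

## Worked example

The package ships a reconstructed reference dataset of 47 active ingredients
(48 formulations — imidacloprid appears as both liquid and slow-release)
registered for sugar cane and its rotation crops. Thresholds are the
published values; application rates and water half-lives are back-computed to
reproduce the published measures and are flagged as reconstructions, not
label-verbatim values.

```python
>>> import pdst
>>> table = pdst.load_reference_table()
>>> results = {r.pai_name: r for r in pdst.risk_results(table)}
>>> r = results["diuron"]
>>> r.effect, r.mobility_persistence
(2478.0, 136.00000000004667)
>>> round(r.aquatic_risk), round(r.aquatic_risk_reported)
(337008, 3370)
```

Diuron needs ~2478 ML/ha of dilution at its maximum rate, scores 136 on
mobility and persistence, and lands at an aquatic risk of 3.4 × 10⁵
(printed as 3370 on the /100 scale) — 14th of the 48 formulations.
Band-spraying 10 % of the field cuts every risk exactly 10-fold; tank mixes
sum component risks as an indicative total:

```python
>>> mix = pdst.TankMix([("diuron", results["diuron"]),
...                     ("hexazinone", results["hexazinone"])])
>>> round(pdst.tank_mix_risk(mix))
948528
```

The same operations are available from a shell:

```console
$ pdst compute --out risk_table.csv
wrote risk_table.csv: 48 formulations (rate bound max, regime broadcast)
$ pdst compare atrazine amicarbazone | head -3
{
  "verdict": "b_dominates",
  "preferred": "amicarbazone",
```

`pdst compare` applies the dominance rule: an alternative that is lower on
*both* axes is preferred outright; otherwise the risk product decides.
`pdst plot` draws the effect-vs-mobility log-log scatter, `pdst derive-etv`
runs the threshold pipeline on a species toxicity table, and
`pdst calibrate` reports the runoff-regression and rank-correlation
statistics behind the mobility model.

## Layout

| module | contents |
|---|---|
| `pdst.registry` | data model, unit conversions, CSV I/O, bundled dataset, synthetic tables |
| `pdst.etv_derivation` | species aggregation, SSD fitting, assessment factors, percentile and reliability policy |
| `pdst.risk_engine` | the two measures, the risk product, spray regimes, tank mixes, ranking and dominance |
| `pdst.calibration` | Spearman tests (exact small-n p-values), the runoff-loss regression, K_OC reconciliation, rate-bound sensitivity |
| `pdst.cli` | the `pdst` command-line interface |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
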