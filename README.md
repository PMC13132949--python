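# bpcentile

Pediatric oscillometric blood-pressure centiles: quantile-regression
reference-table construction on synthetic cohorts, percentile engines for
three reference-model representations, and reclassification concordance
against international guideline systems.

## What it does

* **`bpcentile.synthetic`** — generates child-level cohorts (ages 4–15,
  triplicate integer-mmHg BP readings, LMS-style height/BMI, missing
  weights, register-style exclusion flags) with age- and sex-dependent
  Gaussian BP and an age-widening systolic spread. Fully reproducible from a
  single seed with per-variable sub-streams.
* **`bpcentile.prep`** — protocol mean BP (average of the last two of three
  readings, with fallbacks), LMS z-scores, overweight classification (BMI
  SDS cutoff anchored at BMI 25 at age 18; waist-to-height ≥ 0.5 fallback),
  and deterministic exclusion filtering with a per-reason log.
* **`bpcentile.reference_fit`** — OLS (adjusted R²), restricted cubic
  splines with quartile knots, exact LP quantile regression on the 19-point
  5% grid, integer-mmHg reference tables with non-crossing enforced by
  isotonic rearrangement, and a full-vs-simple (±height) model comparison.
* **`bpcentile.engines`** — percentile assignment under lookup tables
  (categories), Gaussian age/height polynomial equations, or fitted quantile
  sets; guideline classification with age-dependent fixed-threshold
  switches (AAP/ESC/ESH/custom). A Danish pediatric lookup reference ships
  as `danish_2025`.
* **`bpcentile.concordance`** — 2×2 reclassification tables, detection and
  false-negative/positive rates, per-age 95th-percentile mmHg gaps, and
  Bland–Altman limits of agreement.

## CLI

```sh
# full pipeline on a synthetic cohort
bpcentile all --seed 1 --n 1700 --out out/

# or stage by stage
bpcentile simulate --seed 1 --n 1700 --out out/
bpcentile prepare  --cohort out/cohort.csv --bmi-ref out/bmi_reference.csv \
                   --growth-ref out/growth_reference.csv --out out/
bpcentile fit      --prepared out/prepared.csv --out out/
bpcentile classify --prepared out/prepared.csv --guideline danish \
                   --reference danish_2025 --out out/
bpcentile compare  --prepared out/prepared.csv --benchmark danish_2025 \
                   --comparator us_style_demo --guideline esh \
                   --growth-ref out/growth_reference.csv --out out/
bpcentile report   --indir out/
```

Outputs: prepared cohort CSV, exclusion log JSON, quantile fits and
reference table (CSV + JSON), per-guideline classification CSVs, and
concordance reports (JSON + text tables). Every artifact embeds the config
hash and seed; re-running with the same pair is byte-identical.

Reference models are plain JSON with a `type` discriminator
(`lookup` | `gaussian_poly` | `quantile_set`); see
`src/bpcentile/data/*.json` for the two packaged examples. The packaged
`us_style_demo` Gaussian-polynomial coefficients are synthetic stand-ins for
demonstration, not published values.

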