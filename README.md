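# abpscreen

A validation pipeline for unattended automated office blood-pressure (BP)
screening against 24-hour ambulatory blood-pressure monitoring (ABPM).
It covers the full path from raw timestamped cuff readings and triplicate
office sessions to hypertension phenotypes and a diagnostic-accuracy /
agreement report, plus a synthetic circadian-BP cohort generator that
provides ground truth for every downstream stage.

## What it does

- **`abpscreen.synth`** — simulates cohorts with known latent day/night
  pressures, nocturnal dipping, white-coat (positive office offset) and
  masked (negative offset) subpopulations, a realistic device schedule
  (cuff inflations every 20 min by day, 40 min by night), and record-level
  missingness. Writes the raw CSV inputs plus a test-only truth file.
- **`abpscreen.core`** — ingests readings, applies completeness-based QC
  (≥10 daytime readings in 10:00–20:00 and ≥5 nighttime in 00:00–06:00),
  and computes daytime/nighttime window means, time-weighted 24-h means
  (midpoint-interval weighting), and office-session means.
- **`abpscreen.phenotype`** — screen status at the 130/80, 135/85 and
  140/90 mmHg cutoffs (OR rule, non-strict ≥), ambulatory reference status
  (24-h ≥130/80; daytime ≥135/85; nocturnal ≥120/70), the four-way
  sustained / white-coat / masked / normotensive phenotype, and dipping.
- **`abpscreen.stats`** — sensitivity/specificity/PPV/NPV with Wilson,
  Clopper-Pearson or Wald CIs, likelihood ratios with log-method CIs,
  AUROC in both single-cutoff and Mann-Whitney forms, McNemar's test
  (exact and asymptotic), Bland-Altman limits of agreement with the
  Pitman-Morgan trend test, and OLS regression of device differences on
  covariates.
- **`abpscreen.pipeline`** — orchestrates everything into a deterministic
  JSON report with a subject-flow ledger, per-threshold validity tables,
  agreement/correlation blocks, stratified analyses (sex, age group, site,
  BMI category) and sensitivity analyses (include medicated subjects;
  include QC-failing records).

## CLI

```sh
# generate a synthetic cohort (writes subjects/office/abpm_readings/truth CSVs)
abpscreen simulate --n 1000 --seed 1 --out cohort/

# per-subject QC counts and summary means
abpscreen summarize --readings cohort/abpm_readings.csv --out summaries.csv

# per-subject phenotypes at chosen cutoffs
abpscreen classify --summaries summaries.csv --office cohort/office.csv \
    --subjects cohort/subjects.csv --thresholds 130/80,135/85,140/90 \
    --out phenotypes.csv

# full validity / agreement report
abpscreen validate --summaries summaries.csv --office cohort/office.csv \
    --subjects cohort/subjects.csv --reference 24h --strata sex,site \
    --report report.json --tables tables.csv
```

Generator settings can also be given as YAML via `simulate --config`.

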