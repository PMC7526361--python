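# File formats

All tables are comma-separated UTF-8 text with a header row and `.` decimal
marker. Times are in days.

## Patient records (IPD)

`write_ipd` / `read_ipd`. One row per subject.

| column         | type    | meaning                                   |
|----------------|---------|-------------------------------------------|
| arm            | str     | arm label (`A` / `B`)                     |
| age            | float   | years                                     |
| postmenopausal | 0/1     | post-menopausal indicator                 |
| grade2         | 0/1     | tumour grade 2 indicator (grade 1 = ref)  |
| grade3         | 0/1     | tumour grade 3 indicator                  |
| treated        | 0/1     | comparator-treatment (B) indicator        |
| time           | float   | observed time, days                       |
| event          | 0/1     | 1 = event observed, 0 = censored          |

Validation on read: all columns present, numeric `age`/`time`, nonnegative
times, indicator columns in {0, 1}; errors name the first offending row.

## Curve coordinates

`write_curve` / `read_curve`: columns `time_days,survival` — one row per
step corner, starting at `(0, 1)`; the same shape a digitizer export has.

## Numbers-at-risk table

`write_risk_table` / `read_risk_table`: columns `time_days,n_at_risk`,
starting at time 0; counts nonincreasing.

## Aggregates

`write_aggregates` / `read_aggregates`: JSON object with keys `mean_age`,
`var_age` (sample variance), `p_postmenopausal`, `p_grade2`, `p_grade3`,
`n_total` and optionally `total_events`.

`write_publication(pub, dir)` writes the three artifacts as
`<prefix>_curve.csv`, `<prefix>_risk_table.csv`, `<prefix>_aggregates.json`
(default prefix `b_arm`).

## Reconstructed IPD

`write_reconstructed` / `read_reconstructed`: columns `time_days,event`,
plus a provenance sidecar `<path>.provenance.json` marking the records as
reconstructed.

## Study outputs (`umaic run-study --out DIR`)

* `estimates.csv` — per repetition and strategy: `rep, scenario, strategy,
  log_hr, se, hr, ci_low, ci_high, ess, converged`.
* `validation.csv` — per repetition: reconstruction-fidelity hazard ratios
  and CI-covers-one flags.
* `performance.csv`, `validation.csv`, `bias_factor.csv` — aggregate tables.
* `manifest.json` — config (with SHA-256 hash), master seed, package
  version: everything needed to reproduce the run bit-identically.
* `run_log.jsonl` — JSON-lines event log (repetition start/end, exclusions
  with reasons).

## Configuration (YAML)

Top-level keys: `scenario` (1|2), `n_reps`, `seed`, `out_dir`, `arm_a`,
`arm_b` (mappings of ArmSpec fields, e.g. `n`, `age_mean`, `age_range`,
`p_grade1..3`, `weibull_scale`, `beta_*`, `max_followup`, `censor_upper`),
`publication` (`risk_times`, `precision`, `round_times`,
`publish_total_events`, `time_jitter`, `survival_jitter`), `balance_tol`,
`include_omit_em_scenario1`, `bias_factor` (`hr_ud`, `rr_eu`). An empty file
reproduces the shipped defaults; unknown keys are errors.
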