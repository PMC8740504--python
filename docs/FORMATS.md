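# File dialects

All inputs and outputs are plain delimited text (comma-separated by default)
with a required header row. Dates may be given as ISO `YYYY-MM-DD` or as
decimal years; internally one year = 365.25 days.

## Cohort file

One row per subject, columns:

| column        | meaning                                                        |
|---------------|----------------------------------------------------------------|
| `id`          | subject identifier (any string)                                |
| `time`        | follow-up from diagnosis in years, > 0                         |
| `event`       | 1 = died at `time`, 0 = censored at `time`                     |
| `age_dx`      | age at diagnosis in years                                      |
| `date_dx`     | diagnosis date (ISO date or decimal year)                      |
| `std_stratum` | joint covariate cell used for external standardisation         |
| *(others)*    | every remaining column is a rate-table matching key (e.g. sex) |

Column names can be remapped through the `schema` argument of
`refsurv.load_cohort`. Columns named like `entry`, `entry_time`, `start`,
`tstart` are rejected: delayed entry is not supported.

## Population rate table

Long format, one row per cell:

```
age,year,<strata...>,rate
70,2010,m,0.0112
```

* `age`: attained age in completed years (integer); `year`: calendar year
  (integer); `rate`: mortality rate per person-year, >= 0.
* Any additional columns are strata keys; every combination appearing in the
  file must be complete over the full age x year grid.
* Cells are half-open one-year intervals; ages above the oldest row carry it
  forward, years outside the range clamp to the nearest covered year.

## Standard distribution

```
std_stratum,proportion
55-64,0.23
```

Proportions must sum to 1 (tolerance 1e-9).

## Estimate output (tidy)

One row per (time, quantity): `time, quantity, estimate, se, ci_low,
ci_high, mode`. Quantities: `H`, `F` (observed all-cause), `Lambda_R` (net),
`H_R_pop` (reference population part), `H_R`, `S_R`, `F_R_C`, `F_R_O`.
With `--report-times` a wide snapshot at the requested times is written next
to the main table with suffix `.report.csv`.

## Simulation config (YAML)

```yaml
n: 20000
seed: 1
admin_censoring: 6.0          # years; administrative censoring horizon
dropout_rate: 0.0             # exponential dropout rate per year, optional
diagnosis_window: [2008, 2013]
expected: 0.05                # constant rate, or {path: expected.csv}
reference: 0.05               # optional; same forms as expected
standard: {young: 0.5, old: 0.5}   # optional external standard
strata:
  - label: young
    proportion: 0.6
    excess: 0.15              # constant, or {breaks: [0, 1], rates: [0.3, 0.1]}
    age: {uniform: [50, 64]}  # or {fixed: 60}
    rate_keys: {}             # values for the expected table's strata columns
```

## Interval grid dialect

`--intervals start(step)end`, e.g. `0(1/12)10` for monthly intervals over
ten years; the step may be a decimal or a fraction of a year.
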