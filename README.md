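# refsurv

Non-parametric, reference-adjusted and standardised estimation of all-cause
and cause-specific (crude) probabilities of death in the relative-survival
framework used for population-based cancer data.

## The problem

Cancer registries rarely have reliable cause-of-death codes, so
cancer-specific mortality is estimated by *excess* mortality: each
patient's all-cause rate is partitioned as

    h_i(t) = h*_i(t) + λ_i(t),

where h*_i(t) is the background rate read from a population life table
(matched on attained age, calendar year, sex, deprivation, ...) and λ_i(t)
is the excess rate attributed to the cancer. Net-survival estimators
(Pohar Perme, Ederer II, Sasieni–Brentnall) isolate λ but answer a
hypothetical question ("if the cancer were the only possible cause of
death"). Crude probabilities of death — the real-world probability of dying
*of* the cancer, or of something else, by time t — are more interpretable
but unfair to compare across groups, because they mix each group's own
background mortality and covariate profile into the answer.

`refsurv` implements weighted counting-process estimators that keep the
crude-probability scale while making comparisons fair: a common *reference*
rate set h**_i replaces each group's own background rates on the way back
from the excess-hazard scale, and time-fixed weights standardise the joint
covariate distribution to an external standard. With time-dependent weights
w_i(t) = w_i^B · S**_i(t)/S*_i(t), the reference-adjusted marginal
all-cause cumulative hazard is

    Ĥ_R(t) = ∫₀ᵗ Σᵢ wᵢ(s) Yᵢ(s) {dNᵢ(s) − dH*ᵢ(s) + dH**ᵢ(s)} / Σᵢ wᵢ(s) Yᵢ(s),

split into a net part Λ̂_R (the dN − dH* term) and a reference population
part Ĥ_R**; Ŝ_R = exp(−Ĥ_R), and the crude probabilities of death due to
cancer and other causes are the integrals of Ŝ_R(u−) against dΛ̂_R and
dĤ_R**. Setting the reference equal to the expected table recovers
Nelson–Aalen; S** ≡ 1 gives Pohar Perme; w ≡ 1 gives Ederer II; dropping
dH** gives the Sasieni–Brentnall net index — all asserted exactly in the
test suite. A grouped-time (lifetable) approximation computes the same
estimands on interval grids for large cohorts, and a simulator generates
cohorts with known excess hazards and closed-form truths.

Audience: biostatisticians and cancer-registry analysts producing survival
statistics compared across regions, periods, or population subgroups.

## Worked example

Simulate a 5,000-patient cohort with two age strata (excess hazards 0.15
and 0.3 per year, background rate 0.05/y, reference rate 0.04/y,
administrative censoring at 6 years), then estimate the standardised,
reference-adjusted quantities:

```sh
refsurv simulate --config sim.yaml --out-dir data
refsurv estimate --cohort data/cohort.csv --expected data/expected.csv \
    --reference data/reference.csv --standard data/standard.csv \
    --mode reference_adjusted --report-times 1,5 \
    --out estimates.csv --manifest manifest.json
```

The report snapshot (`estimates.report.csv`) printed for this seed:

```
       F_R_C  se_F_R_C  lo_F_R_C  hi_F_R_C   F_R_O     S_R       F
time
1.0   0.2031    0.0066    0.1906    0.2163  0.0350  0.7619  0.2348
5.0   0.5977    0.0077    0.5825    0.6128  0.1118  0.2906  0.7037
```

Reading the 5-year row: under the common reference rates and the standard
age distribution, an estimated 59.8% (95% CI 58.3–61.3%) of patients die
of the cancer within five years (`F_R_C`), 11.2% die of other causes
(`F_R_O`), and 29.1% are still alive (`S_R`); the unadjusted observed
all-cause probability of death is 70.4% (`F`). The closed-form truths for
this design (`refsurv truth --config sim.yaml --times 5`) are 0.6027 for
the cancer and 0.1126 for the other-cause probability — both inside one
standard error of the estimates. `refsurv compare` assembles the same
quantities for several groups sharing one reference table and standard
(observed | reference-adjusted | reference-adjusted + standardised | net),
and `refsurv validate` lints input files. File dialects are documented in
`docs/FORMATS.md`, the statistical details in `docs/methods.md`.

The same analysis from Python:

```python
from refsurv import estimate, load_cohort, load_ratetable

subjects = load_cohort("data/cohort.csv")
expected = load_ratetable("data/expected.csv")
reference = load_ratetable("data/reference.csv")
series = estimate(subjects, expected, reference,
                  standard={"55-64": 0.5, "65plus": 0.5},
                  mode="reference_adjusted")
print(series.at([1.0, 5.0])[["F_R_C", "F_R_O", "S_R"]])
```

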