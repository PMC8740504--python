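# Methods

## Setting and model

Population-based cancer survival works in the relative-survival (excess
mortality) framework because individual causes of death are unavailable or
unreliable. Each subject's all-cause mortality rate is assumed to decompose
as

    h_i(t) = h*_i(t) + lambda_i(t),

where h*_i is the background (expected) rate read from a population life
table matched on attained age, attained calendar year and demographic keys,
and lambda_i is the excess rate attributed to the cancer. Equivalently, on
the survival scale S_i(t) = S*_i(t) R_i(t) with R_i the relative survival.

Comparisons of crude (real-world) probabilities of death across groups are
confounded by two things: different background mortality and different
covariate mixes. The estimators here remove both while staying on the
interpretable crude-probability scale: a common *reference* rate set h**_i
replaces each group's own background rates when converting back from the
excess-hazard scale, and time-fixed standardisation weights align the
covariate distribution with an external standard. Differences between
groups then reflect differences in excess mortality only.

## Estimators

Let N_i(t) count subject i's death, Y_i(t) = I(T_i >= t) the at-risk
indicator, and let

    w_i(t) = w_i^B * S**_i(t) / S*_i(t)

with S*_i = exp(-H*_i), S**_i = exp(-H**_i) the expected survival under the
matched and the reference rates, and w_i^B the time-fixed standardisation
weight (ratio of the external standard's share of subject i's joint
covariate cell to the analysed group's own share). At each unique event
time s, with expected-hazard increments accrued over the interval since the
previous event time while at risk,

    dLambda_R(s) = sum_i w_i(s) Y_i(s) {dN_i(s) - dH*_i(s)} / sum_i w_i(s) Y_i(s)
    dH_R**(s)    = sum_i w_i(s) Y_i(s)  dH**_i(s)           / sum_i w_i(s) Y_i(s)
    dH_R(s)      = dLambda_R(s) + dH_R**(s).

Cumulating gives the net cumulative hazard Lambda_R, the reference
population part H_R**, the reference-adjusted all-cause cumulative hazard
H_R, all-cause survival S_R = exp(-H_R), and the crude probabilities of
death due to cancer and other causes as integrals of S_R(u-) against
dLambda_R and dH_R**.

Special cases, recovered exactly and asserted in the test suite:

* reference = expected tables, unit pre-weights: H_R is the Nelson–Aalen
  all-cause estimator;
* zero reference hazard (S** = 1): Lambda_R is the Pohar Perme net
  cumulative hazard (1/S* weights);
* unit weights: Lambda_R is the Ederer II net estimator;
* ratio weights with the dH** term dropped: the Sasieni–Brentnall net index.

Why the weights work: in the population limit the weighted at-risk
composition of stratum g is proportional to pi_g^std R_g(s) S**_g(s), i.e.
to the stratum's subject-level reference-adjusted survival, which makes
exp(-H_R(t)) equal the standard-weighted *mixture* of stratum survival
functions, and the crude probabilities the corresponding mixtures of
stratum-level cause-specific cumulative incidences. The simulator's truth
module computes exactly these mixtures.

## Numerical conventions

* **Weight timing.** w_i(s) is evaluated at the event time s (right
  endpoint of the increment). Any convention inside the inter-event
  interval vanishes as increments shrink; one is fixed for reproducibility.
* **Crude-probability allocation.** The displayed identities
  S_R = exp(-H_R) and F = integral of S_R(u-) against the cause increments
  are not exactly mutually consistent at finite increments. The default
  allocation splits the exact total increment
  S_R(u-) - S_R(u) = S_R(u-)(1 - e^{-dH}) between causes in proportion to
  dLambda_R and dH_R**, implemented as
  dF_C = S_R(u-) * dLambda_R * (1 - e^{-dH})/dH with the factor tending to
  1 as dH -> 0. This guarantees F_R^C + F_R^O = 1 - S_R exactly at every
  grid point, agrees with the literal integral to second order, and (unlike
  a naive ratio split) passes each cause's signed contribution through even
  when the total increment is zero, which matters on fine grouped grids.
  `allocation="literal"` reproduces the plain integrals verbatim.
* **Rate-table cells.** Attained age floors to completed years; calendar
  year is the civil year; both cells are half-open; rates are constant
  within a cell (the within-cell convention is not standardised across
  software; constant-within-cell matches national life-table construction).
  One year = 365.25 days. Ages above the oldest row carry it forward;
  years outside the covered range clamp. A reference table representing a
  single calendar year's rates is applied with the `frozen_year` flag: the
  attained-age progression is kept, the year lookup is held fixed.
* **Ties.** Deaths at a time are processed before censorings at the same
  time (Y_i(t) = I(T_i >= t)).
* **Degenerate inputs.** A cohort with no deaths yields flat estimates with
  a warning; an event time with zero weighted risk (impossible when all
  weights are positive) is a hard error; empty standard cells are dropped
  with renormalisation and a warning.

## Variance and confidence intervals

Weighted cumulative hazards get Poisson-increment variances,

    Var{Lambda_R(t)} = sum_{s<=t} [sum_i w_i(s)^2 dN_i(s)] / [sum_i w_i(s) Y_i(s)]^2,

with expected-hazard increments treated as deterministic (they are
predictable integrals of known rates). S_R and the crude probabilities use
influence-function (delta-method) propagation: a unit of death mass at s
moves F_R^C(t) by [S_R(s-) - (F_R^C(t) - F_R^C(s))] / D(s), and F_R^O(t)
by -(F_R^O(t) - F_R^O(s)) / D(s), where D is the weighted number at risk;
the resulting sums are computed with O(m) cumulative-sum identities.
Confidence intervals are on the log scale for cumulative hazards and the
log(-log) scale for probabilities, clipped to [0, 1]. The construction is
validated by simulation: the 95% interval for the 5-year crude cancer
probability achieves nominal coverage within Monte-Carlo error (see the
coverage test), and at n = 5,000 the mean estimated SE of both crude
probabilities matches the empirical SD of the estimates within ~2%.

Point estimates and variances are invariant under rescaling of all weights
(degree-zero homogeneity), also asserted in the tests.

## Grouped-time (lifetable) approximation

For large cohorts or interval-recorded data the same estimands are computed
on a pre-specified grid (e.g. months). Within each interval, the weighted
death proportion uses the classical actuarial denominator (full credit for
deaths, half credit for within-interval censorings) and is converted to a
hazard increment by -log(1 - q), the standard actuarial transform; this
matches the continuous-time harmonic sum over the interval's deaths to
second order at any interval width. Expected-rate terms accrue exact
person-time and are divided by the average weighted at-risk (half credit
for any within-interval exit), which makes them exact for constant rates.
The expected-survival-ratio weight is evaluated once per interval at the
midpoint (second-order accurate for smooth expected survival). On a
simulated n = 20,000 cohort the monthly grid reproduces the continuous-time
5-year estimates to a few 1e-5 and the deviation is non-increasing under
grid refinement from yearly through monthly to daily; with the interval
grid aligned so that report times are boundaries, the residual floor is
the O(1/Y) per-death difference between the grouped and event-by-event
denominators.

## Synthetic cohorts and truths

The simulator draws cohorts under the exact model the estimators assume:
per-stratum piecewise-constant excess hazards added to table-derived
expected hazards, ages and diagnosis dates drawn per stratum (defaults:
diagnosis dates uniform on [2008, 2013)), administrative censoring at a
fixed horizon plus optional exponential dropout. Event times are drawn by
exact inversion on the merged breakpoint grid (age birthdays, calendar new
years, excess-hazard pieces) — no discretisation, no rejection. Cause
labels are never attached to the cohort the estimators see; they can be
written to a separate debug file.

For specs whose hazards are constant in time given the stratum (constant
or piecewise-in-t excess rates; constant expected/reference rates), the
estimands have closed forms, e.g. per constant piece
F_C = lambda/(lambda+mu) * [S(start) - S(end)], and marginal truths are
stratum mixtures under the sample or the standard proportions. Truths for
age-varying rate tables combined with non-degenerate age distributions are
deliberately unsupported rather than approximated.

What the simulations do not emulate: real registries have late entry,
reporting delay, age-dependent excess hazards, informative censoring and
life-table misclassification. Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not robustness
to violations of those assumptions.

## Known limitations and scale choices

* Net-type cumulative hazards (and hence the crude cancer probability) are
  not guaranteed monotone in finite samples: a long gap between events can
  accrue more expected hazard than a single death contributes. This is a
  property of the estimand's non-parametric estimator, not a bug; the
  structural-invariant tests generate cohorts in the regime the method
  targets (event intensity dominating expected accrual between events),
  where monotonicity holds.
* The continuous-time engine re-evaluates every at-risk subject's weight at
  every unique event time, which is O(sum_s Y(s)); an n = 20,000, ~15,000
  event-time analysis takes a few seconds. Verification runs use
  n = 20,000 for recovery/fair-comparison/convergence checks, 500
  replicates of n = 2,000 for coverage, and 10 cohorts of n = 500 for the
  exact collapse checks.
* Delayed entry (period analysis), multiple records per subject,
  model-based (regression) standardisation, rate-table smoothing and
  relative-survival-ratio outputs are out of scope.
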