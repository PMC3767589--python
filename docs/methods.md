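# Methods

This note records the modelling choices, defaults and limitations of
saltshift in one place. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sodium intake from spot urines

The Tanaka estimator is implemented exactly as published: predicted 24-h
creatinine `PrCr24 = −2.04·age + 14.89·weight(kg) + 16.14·height(cm) −
2244.45` mg/day, and `Na24 = 21.98·(spotNa/(10·spotCr)·PrCr24)^0.392`
mEq/day, with spot sodium in mEq/L and spot creatinine in mg/dL. The
constants are hard-coded defaults but exposed through `TanakaCoefficients`
so other spot-urine estimators can be swapped in by parameter change.
Anthropometrics for which the creatinine predictor is non-positive are a
domain error, not a clipped value.

Two aggregation paths exist because survey practice is ambiguous:
`per_sample` (default) estimates each participant with their own
anthropometrics and averages the estimates — the only path that actually
uses individual covariates — while `mean_concentration` averages
concentrations and anthropometrics per sex first and applies the estimator
once. Intake is summarised by sex only and treated as constant over ages
35–84: Argentine data show only small age differences in consumption, and
the intervention acts multiplicatively on the mean.

Unit conventions: 23 mg sodium per mEq (molar mass); exactly 2.5 g NaCl per
1000 mg sodium, the anchor that makes the 2000 mg/day guideline equal 5 g of
salt.

## Scenarios and blood-pressure dose-response

Scenario schedules are *additive* fractions of baseline intake (4% + 4% =
8%; ten 4% steps = 40%), not compounded multiplicatively; the cumulative
reduction is held constant after the schedule ends. The SBP dose-response is
linear in grams of salt removed: 1.87 mmHg/g for the subgroup that is
hypertensive **or** aged ≥ 65 (the union reading; the threshold is
inclusive), 1.17 mmHg/g for everyone else. Hypertension status is fixed at
baseline — a treated person whose SBP falls below threshold keeps the high
slope — because the cell structure is static. SBP shifts phase in with the
schedule from the first year they accrue and are applied to cell-mean SBP
before risk evaluation. Treated and untreated hypertensives receive the same
slope.

## Risk engine

Annual first-event probabilities come from sex- and age-band-specific
logistic equations evaluated at cell-mean covariates (prevalence fractions
for binary factors). Evaluating the logistic at the mean rather than
averaging individual risks is a first-order approximation; it is the
standard cell-model simplification and is documented as such. The CHD
covariate set is {age, SBP, smoking, LDL, HDL, diabetes, antihypertensive
use}; stroke uses {age, SBP, smoking, diabetes}; both are enforced at load
time. Age bands default to decades (35–44 … 75–84) and are configurable.
Antihypertensive use enters as a main effect only.

No claim is made to reproduce any published coefficient values: the
estimation data are not distributable. The synthetic generator instead
*solves* each band intercept so that the probability at band-mean covariates
equals a realistic incidence target (CHD rising from ~0.2% to ~2.6% per
year in men across the bands; stroke similar but lower), with slope
coefficients of conventional magnitude (e.g. 0.017–0.020 per mmHg SBP).
This guarantees probabilities inside the sanity band (1e-6, 0.5) by
construction. All results flow from whichever coefficient file the user
supplies.

## Cohort engine

Deterministic expected-value propagation over cells (age 35–84 in 1-year
steps × sex × {normotensive, hypertensive-untreated, hypertensive-treated} ×
{healthy, post-MI, post-stroke, post-both}); no individual-level Monte
Carlo. One cycle = one calendar year, events evaluated at start-of-cycle
covariates, no half-cycle correction. The "ten years, 2013–2023" window is
ten annual cycles (2013..2022 inclusive).

Competing exits within a cycle use a product-of-survivals decomposition:
total exit probability `1 − Π(1 − p_k)`, shared among causes in proportion
to their marginal probabilities, so joint exits never exceed the cell. With
a single active cause this reduces to `n·p`, which is what makes the
1000-person worked example (100 events, 30 day-1 deaths, 7 late deaths,
63 history entrants) exact.

Bridge: day-1 case fatality, then 28-day case fatality conditional on
surviving day 1; 30-day survivors enter the matching history state in the
same cycle. A configurable `mi_fraction_of_chd` (default 0.6) splits first
CHD events into MI versus angina; the MI ledger column counts fatal plus
non-fatal MI, first and recurrent, while angina is tracked in its own
column. History-state CVD deaths are attributed to CHD (post-MI), stroke
(post-stroke) or split 50/50 (post-both). The post-both rate set defaults to
the elementwise maximum of the post-MI and post-stroke sets.

Persons reaching age 85 exit to an aged-out tally (not deaths); a new
35-year-old cohort enters each year, all healthy, distributed over
hypertension strata. The conservation identity
`persons(t+1) + deaths(t) + aged_out(t) = persons(t) + incoming(t)` holds by
construction; tests assert it at 1e-12 relative tolerance, i.e. to
floating-point rounding. The ledger counts every death of a simulated
person, so `other_deaths` can rise slightly under an intervention
(competing-mortality rebound); the monotonicity and scenario-dominance
guarantees therefore apply to the event and CVD-death categories and to
total deaths, not to non-CVD deaths.

## Calibration

A single common odds multiplier (default) moves the CHD and stroke
intercepts by `ln f` and the history-state CVD death probabilities by
`p' = pf/(1 − p + pf)`; slopes and all non-CVD rates are untouched.
The search is Brent root finding on `log f` over multiplier bounds
[1/50, 50], targeting the last observed year of the adjusted death series
(definite + `garbage_fraction` × poorly defined counts; default fraction
1.0, i.e. all listed poorly-defined deaths counted, since no canonical
fraction exists — it is a required analysis input). Projected CVD deaths
are monotone in the multiplier on the shipped presets (asserted in tests),
which justifies bracketing. A least-squares mode over the whole overlapping
series is available. The reported discrepancy is the last-year relative
error; exceeding the 5% default tolerance raises rather than returning
silently.

## Synthetic data

The generators exist so every pipeline stage is testable without data
downloads; they emulate the *structure* of the real inputs, not Argentina
itself. Families: truncated normals for continuous measurements, lognormal
for spot creatinine and for vital-statistics noise, Bernoulli-style
prevalences entering as cell means. The spot-urine distribution parameters
were set once, against the estimator, so the default 760-person cohort's
per-sex means land near the survey values (4832/3983 mg/day); the test
tolerance (10%) reflects sampling error at n = 760. Generated files carry
`#` provenance headers (seed, preset, version).

Two presets: `desk` (200 000 persons aged 35–84, the default for tests and
calibration work) and `full` (13.7 million, Argentina-magnitude, ~560 000
incoming 35-year-olds/year). Because propagation is expected-value, presets
differ only by a population scale factor — identical rates, identical
runtime — and the full preset's ten-year baseline death total sits in the
published order of magnitude (checked only to within ±50%; absolute event
tables are not a target). Passing tests on synthetic data demonstrate the
arithmetic and the invariants, not the accuracy of any real-world input:
regional heterogeneity, age-varying intake, secular risk-factor trends and
consumer compensation are all outside what the generator emulates.

## Numerical choices and degenerate inputs

* Probabilities are kept in closed form (`scipy.special.expit`); an
  intercept of −∞ is a legitimate "rate off" switch used by the
  zero-rate preset.
* Bisection/Brent tolerance is 1e-10 on the log multiplier; recovery tests
  require 1% agreement, comfortably inside that.
* A cell whose combined exit probabilities exceed 1 raises a
  `ParameterError` naming the cell rather than silently renormalising.
* Empty scenario schedules are valid and reproduce the baseline ledger
  bit-for-bit; zero sodium reduction gives exactly zero SBP shift.
* Avoided-event tables report a companion column rounded to the nearest 500
  (country-scale reporting granularity) alongside the unrounded values.

## Known limitations

Costs, QALYs and discounting are out of scope, as are cause-of-death
redistribution by ICD code group (pre-aggregated counts are taken as given)
and any refitting of risk equations. The cell-mean logistic approximation
understates risk convexity; the 1-year cycle without half-cycle correction
slightly biases event timing; the post-both rate convention (max of the
single-history sets) is a modelling default, not an estimate.
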