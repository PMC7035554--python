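# Methods

This note records the statistical model, the generator that stands in for
real schedule data, the numerical choices, and the limits of what the
test suite demonstrates.

## Outcome and data model

A record is one operation with five clock times at minute resolution:
wheel-in, anaesthesia, first cut, last suture, wheel-out. The outcome is
the cut-to-suture interval in minutes, modelled on the natural-log scale
(log-normal durations; `exp(4.97) ≈ 144` minutes is a typical baseline
mean). Natural log, not base 10: minute-scale interpretations are
`exp(intercept + coefficient)`.

Clock times carry no date, so a suture time that clock-precedes its cut
time is resolved as a midnight crossing (+24 h). A consequence is that a
genuinely mis-ordered timeline cannot be distinguished from a very long
stay; validation therefore bounds the resolved wheel-in-to-wheel-out span
at 24 h and rejects records beyond it. Cut-to-suture durations are also
capped (default 24 h) as a plausibility screen; the cap is configurable
because cleaning rules for implausible durations are a judgement call,
not a property of the data.

Slashed dates are parsed day-first by default (configurable). When an
input file carries its own weekday column it is checked against the
weekday computed from the date; the policy on mismatch is configurable
(`strict` error, `warn`, `ignore`) because printed schedule extracts are
commonly internally inconsistent by one day — the bundled sample-data
test documents exactly this case.

## Schedule covariates

From the realized schedule the feature stage derives, per record:
surgeon daily caseload `k`, OR daily workload, and the position label
`k~j` (j-th of k). Ordering within a surgeon-day is by cut time —
the position effect is about when the surgeon operates — with ties broken
by wheel-in time and then record id so the ordering is total and
deterministic. The caseload is by construction the `k` of the position
label; the two encodings are exactly collinear, which is why the two
main-effects models carry one each and never both.

## Change-point estimation

The OR-workload effect is a continuous one-knot piecewise-linear (hinge)
term `s_lo·min(x,c) + s_hi·(x−c)+`, estimated jointly with all other
model-I covariates, not on the marginal relationship. Two estimators:

* **Iterative linearization.** At a working knot `c` the model is
  augmented with the first-order expansion term `−1[x>c]`; after an OLS
  refit the knot moves by the ratio of that term's coefficient to the
  slope-difference coefficient. Raw updates can oscillate or jump basins
  when the kink is weak, so the update is damped (step halving until the
  residual sum of squares improves) and the iteration is restarted from
  every local minimum of a coarse profile scan (step 0.25), keeping the
  lowest-RSS solution. Tolerance 1e−4 on `c`, at most 50 iterations;
  non-convergence is reported in the result, not raised.
* **Grid profiling.** Exhaustive RSS profiling over a grid of knots
  (default step 0.05). This is the slow, global oracle; the contract,
  asserted on repeated random datasets, is that the iterative estimator
  lands within one grid step of the grid minimiser whenever it converges.

The knot is continuous even though the workload is an integer count, so
the RSS profile is piecewise smooth with kinks at the data values —
the reason local minima on either side of an integer can nearly tie and
the reason the multi-start safeguard exists. The search interval excludes
the outer 5% of the covariate range so both segments keep support. With
fewer than three distinct workload values the knot is not identifiable
and the fit refuses to run. The fit also reports a t-test of equal
segment slopes; when that test is not significant at 5% the result
carries a "no change point" flag (data with a genuinely linear workload
effect should and do raise it).

The pipeline estimates the knot once, on the model-I covariate set, and
then holds it fixed for the reported model-I/II coefficient tables
(two-stage presentation). The reported slope CIs at the fixed knot do not
propagate knot uncertainty.

## Regression models and reporting

All models are OLS on log minutes with reference-coded categoricals:
weekday (reference Saturday), surgeon / surgery type / anaesthetist
(reference = most frequent level). Anaesthetist is included by default
and can be dropped by config. Classical homoskedastic standard errors,
t-based 95% CIs, and display codes `***/**/*/&/$` at
0.001/0.01/0.05/0.1. Hypothesis verdicts (the structured summary the
pipeline emits separately from the tables) use a stricter configurable
threshold, default 0.005, since a display code is not a decision rule.
Rank deficiency is detected before fitting and reported with the names of
the aliased terms.

The interaction model extends model II with surgeon-by-position product
terms. Empty cells, and cells whose column is aliased with the base
design (a rare cell that coincides with a single surgeon-day does this),
are dropped with a logged notice and recorded on the fit — the same
behaviour as R's singular-fit `NA` coefficients, chosen so that sparse
but estimable designs still fit.

LASSO selection standardizes each design column (dummies penalised
separately; grouped selection was considered and left out since simple
LASSO is the default practice and the grouping structure here is weak),
centres the outcome, and picks the penalty by 10-fold cross-validation
with a seeded shuffle so selection is deterministic given the seed.
`alpha=0` falls back to plain least squares (selects everything);
explicit large `alpha` empties the selection.

Minute-scale reporting rounds to whole minutes; unrounded values are
always available (`rounded=False`).

## The synthetic generator

The generator emulates the structure of an operation-level schedule from
one busy surgical department; defaults (all configurable):

* ~2,451 operations over 34 months from January 2014; weekday mix
  concentrated Tuesday–Friday with sparse Sunday/Monday operating.
* Six surgeons with case shares 37.5/20.7/19.8/12.1/6.9/3.1% (A most
  frequent and the reference); eleven surgery types with the majority
  type at ≈ 38% of cases.
* Surgeon-day caseloads 1–5 with case shares 24.9/39.9/25.0/9.1/1.2%.
  The number of surgeon-days at each caseload is planned
  deterministically (largest-remainder) so the realized case mix matches
  the configured one to within sampling of the calendar assignment; the
  test suite checks agreement within 2 percentage points.
* OR-day loads 1–6 with nominal case shares 8/20/30/27/9/6%. OR loads
  must partition each day's total, so they are chosen by a greedy
  deficit rule that tracks the configured mix; the rare busy levels 5–6
  are what make the workload profile's upper CIs wide.
* Effects on the log scale: intercept 4.97; hinge slopes −0.067/+0.109
  with the knot at 4; surgeon-caseload slope −0.061 (in `linear` mode)
  or a per-label position-effect table (in `position` mode — the two are
  collinear, so one dataset embodies one of them); surgeon, type and
  weekday effect tables; optional surgeon-by-position interaction
  effects; anaesthetist effects default to zero.
* Noise: `log T = linear predictor + N(0, σ)` with σ = 0.45, which puts
  the main-effects adjusted R² in the weak-signal regime (≈ 0.15–0.2)
  these schedules live in.

Clock synthesis: each OR's first case enters 08:00–09:00; anaesthesia
follows wheel-in by 10–20 min, cut follows anaesthesia by 20–50 min; the
next case enters after the previous one leaves plus a 30-min turnover.
Cases are realized in projected cut-time order across ORs (and a
surgeon's cut times are kept distinct within a day), so the j-th applied
position effect is exactly the j-th realized cut of that surgeon's day.
Durations are rounded to whole minutes when the suture time is
back-filled; this rounding is the only discrepancy between truth and data
at σ = 0, which is why the zero-noise "exact recovery" checks use a
0.02 log-minute tolerance and adjusted R² > 0.995 rather than machine
epsilon.

What the generator does not model: surgeon learning or drift over the 34
months, emergencies and cancellations, planned-versus-actual schedule
gaps, dependence between surgeon, OR, weekday and type beyond what the
workload construction induces, and any clinical case-mix covariates (age
and sex are carried but carry no effect). Passing recovery tests
therefore demonstrate that the estimators are calibrated for the assumed
log-linear, independent-noise regime — not that real schedules satisfy
those assumptions.

## Recovery experiments

`recovery_experiment` repeats generate → ingest → features → change point
→ model over child seeds and scores per-coefficient bias, RMSE and 95%
CI coverage, plus the distribution of the estimated knot. The scored
model is fitted at the generating knot: hinge slopes at different knots
are different estimands, so slope-CI calibration is only meaningful
there; knot recovery is scored separately through `c_hat`. At the default
conditions (100 replicates, n ≈ 2451) every coefficient's coverage sits
in the low-to-mid 90s and the mean knot estimate lands within 0.2 of the
generating value of 4; individual-replicate knot estimates scatter with
sd ≈ 0.27 and a slight right skew (when noise flattens the kink, the
sparse upper segment constrains the knot only weakly). Bias checks allow
for the Monte Carlo standard error of a 100-replicate mean on top of the
0.01 log-minute bound, because the rare-category coefficients' replicate
noise is of the same order as the bound itself.

Problem sizes used by the test suite — 100 replicates for calibration, 20
datasets for the iterative-versus-grid contract, 15–20 replicates for the
selection and interaction simulations — were chosen as the smallest runs
whose pass/fail verdicts are stable under the binomial noise of the
quantity being checked.

## Known limitations

* OLS with homoskedastic errors is the contract; robust or mixed-effects
  inference (random surgeon effects) is out of scope.
* Exactly one change point is entertained, matching the V-shaped workload
  profile; no multiple-knot search and no formal existence test beyond
  the slope-difference t-test.
* The two-stage reporting (estimate knot, then fit at it) understates
  slope CI width slightly by ignoring knot uncertainty.
* The generator's independence assumptions are explicit configuration,
  not an inferred property of any real hospital.
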