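# orduration

Analysis of clinical and nonclinical effects on operative duration in
surgical schedules.

Operating rooms (ORs) are among the most expensive resources a hospital
runs, and scheduling them well requires understanding what drives the
length of an operation. The clinical drivers — the procedure being
performed, the surgeon performing it — are well known. This package
implements an analysis pipeline for the *nonclinical* drivers that can be
read off the schedule itself: how many operations a surgeon performs in a
day, where an operation falls in that surgeon's daily sequence, how many
operations share the OR that day, and the day of the week. The intended
users are health-services and OR-operations researchers working with
operation-level schedule extracts (one row per operation, with wheel-in,
anaesthesia, cut, suture and wheel-out clock times).

## The model

The outcome is the cut-to-suture time `T` in minutes. Because operative
durations are right-skewed, the models are ordinary least squares on the
natural log:

    log T = β₀ + Σ βⱼ xⱼ + s_lo · min(x_OR, c) + s_hi · max(x_OR − c, 0) + ε

where the `xⱼ` are reference-coded categorical covariates (weekday,
surgeon, surgery type, anaesthetist) plus the surgeon-workload term, and
`x_OR` is the OR's daily workload (surgeries in that OR that day). The OR
workload enters through a continuous one-knot hinge: below the breakpoint
`c` the effect has slope `s_lo`, above it slope `s_hi`. The breakpoint is
estimated jointly with the full covariate model by iterative
linearization (with an exhaustive grid search over `c` kept as an
independent oracle — the two must agree to within one grid step).

Surgeon workload enters in one of two exactly collinear forms, so two
models are fitted:

* **model I** — the daily caseload `k` as a continuous count;
* **model II** — the position label `k~j` (the j-th surgery of a day with
  k surgeries by that surgeon) as a categorical with reference `1~1`.

A surgeon-by-position interaction model extends model II, and LASSO with
seeded cross-validation provides variable selection. Because the outcome
is a log, any coefficient `b` is a multiplicative effect: the implied
mean duration is `exp(β₀ + b)` minutes, and `exp(β₀) − exp(β₀ + b)` is
the difference from the baseline in minutes.

The schedule data such analyses run on are typically too sensitive to
share, so the package ships a first-class synthetic schedule generator
(`orduration.synthetic`) that emulates the structure of a real thoracic
surgery department — ~2,451 operations over 34 months, six surgeons,
eleven surgery types, 1–5 cases per surgeon-day, 1–6 per OR-day,
log-normal durations with additive log-scale effects — plus a
parameter-recovery harness that scores bias, RMSE and CI coverage of
every coefficient against the generating truth.

## Worked example

```python
import orduration as od

df, truth = od.generate_frame(od.SyntheticConfig())   # default conditions, seed 7
bundle = od.run_pipeline(df)

seg = bundle.segmented
print(f"change point c_hat = {seg.c_hat:.2f}")
print(f"slopes: {seg.slope_lo:.3f} below, {seg.slope_hi:.3f} above")
t = bundle.model_count.table
print(t.loc[["const", "surgeon_daily_n", "surgeon[F]"], ["estimate", "p", "code"]])
```

prints

```
change point c_hat = 3.96
slopes: -0.064 below, 0.104 above
                 estimate             p code
const            4.962463  0.000000e+00  ***
surgeon_daily_n -0.061086  7.995859e-10  ***
surgeon[F]      -0.338428  9.431443e-10  ***
```

The estimated change point sits at ≈ 4 surgeries per OR-day: duration
*falls* by about 6% per additional OR case below the knot and *rises* by
about 10% per case above it, so the workload–duration relationship is
V-shaped rather than monotone. The surgeon-workload coefficient −0.061
means each additional case in a surgeon's day shortens the expected
duration by about 6%. On the minute scale,

```python
od.backtransform_mean_minutes(4.97, -0.206)   # -> 117.0
od.backtransform_delta_minutes(4.97, -0.094)  # -> 13.0
```

turn an intercept of 4.97 log-minutes and a coefficient into the implied
mean duration (117 minutes) and the difference from baseline (13 minutes
shorter).

A CLI mirrors the library: `orduration generate | run | segment |
fit-model-1 | fit-model-2 | fit-interactions | select-vars`.

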