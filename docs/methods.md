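# Methods

## Model

Hemoglobin glycation is modelled as a single first-order balance on the
glycated fraction `A(t)` of the red-cell hemoglobin pool:

    dA/dt = K·g(t)·(1 − A) − k_age·A

* `g(t)` — extracellular glucose, mg/dL, supplied by CGM readings.
* `K` — apparent glycation constant, per day per mg/dL. It lumps the
  intrinsic glycation rate constant together with the cell's glucose-uptake
  scaling into one identifiable parameter; intracellular glucose is treated
  as proportional to extracellular glucose rather than as a separate
  dynamic compartment (its equilibration is fast relative to the weeks-long
  glycation timescale).
* `k_age` — red-cell turnover rate, per day. The pool is assumed
  well-mixed with age-independent removal, so turnover, lifespan and mean
  cell age interconvert as `2·MA = L = 1/k_age`. Reticulocyte maturation,
  age-structured survival and glucose-dependent removal are not modelled.

At constant glucose the fixed point is `A_ss = K·g/(K·g + k_age)`.
Equating the glycaemic drive `K·g` implied by a laboratory value `H` at the
individual's turnover with the drive at a reference turnover yields the
adjustment

    aHbA1c = H / (H + (k_ref/k_age)·(1 − H)),

an exact algebraic identity between steady states (verified to 1e-12 in the
test suite). Its small-`H` linearisation is `aHbA1c ≈ (k_age/k_ref)·H`,
with relative error bounded by `H/(1−H)`. The adjustment is asymmetric:
shortening the lifespan below the reference moves aHbA1c further than
lengthening it by the same number of days.

## Reference turnover and units

The reference is defined as a lifespan of exactly 106 days, i.e.
`k_ref = 1/106 ≈ 0.9434 %/day` (often quoted rounded as 0.94 %/day; defining
the reference through the rounded rate instead would shift adjusted values
by ~0.01 NGSP points and change some one-decimal presentations). It is a
default, overridable per call and via `--reference-lifespan`.

All internal HbA1c values are NGSP glycated fractions in (0, 1). NGSP % ↔
IFCC mmol/mol uses the master equation `IFCC = 10.929·(NGSP% − 2.15)`; the
IFCC adjustment route converts to fraction, adjusts, and converts back.
Glucose is mg/dL internally (18.016 mg/dL per mmol/L). Rounding — one
decimal for NGSP %, integer for IFCC — happens only at the presentation
layer; note that because printed clinical values are themselves rounded,
feeding a rounded IFCC input (e.g. 60 mmol/mol vs its unrounded NGSP twin
7.6%) can shift the rounded output by one unit.

## Integration scheme

HbA1c dynamics have a time constant of weeks, so the default scheme
aggregates CGM readings to daily mean glucose (a calendar day counts when
at least 50% of its expected readings, from the trace cadence, are valid)
and advances `A` with the exact solution of the linear ODE under
piecewise-constant forcing:

    A_{d+1} = A_ss,d + (A_d − A_ss,d)·exp(−(K·g_d + k_age))

This is unconditionally stable, keeps `A` in (0, 1) for positive inputs,
and is exact for the daily forcing — sub-day substepping changes endpoints
by < 1e-12 (tested). Because the model is linear in `g`, within-day
excursions influence `A` only through the daily mean to first order. A
per-reading scheme is available for sensitivity checks. Runs of missing
days up to 2 are bridged by linear interpolation of daily means; longer
runs make the stretch ineligible.

## Estimation

The unit of information is the *data section*: two laboratory HbA1c draws
connected by CGM. The model is anchored at the section's first draw
(treating it as exact initial condition — the first laboratory value is
used as information, not fitted) and integrated to the second; the
residual is the difference at the end draw. All of a subject's eligible
sections are fitted jointly with shared `(k_age, K)` by bounded
least squares (`scipy.optimize.least_squares`, TRF) in log-parameter
space, `k_age` bounded so the lifespan stays in 50–180 days, from a
multi-start grid: lifespans {60, 100, 160} days crossed with glycation
constants seeded by inverting the steady state at the section's mean
glucose and scaled by {0.5, 1, 2}.

Two estimator details matter in practice:

* **Multiple exact roots.** With two sections the fit is a 2-equation /
  2-unknown system that can admit more than one numerically exact solution
  (observed on synthetic data: a subject with true lifespan 79.7 days whose
  sections were also exactly interpolated at 59.3 days). Among multistart
  solutions whose cost ties the best, the fit deterministically reports the
  one with turnover closest to the 106-day population reference.
* **Convergence definition.** A fit counts as converged only when the
  optimum lies strictly inside the lifespan bounds (margin 0.5 days);
  bound-pinned solutions are excluded as `lifespan_out_of_bounds`. Every
  result is either converged or carries an explicit exclusion reason — no
  silent NaNs.

Eligibility gates (all configurable in `FitConfig`): coverage ≥ 70% of
section days with a valid daily mean; no missing run longer than 2 days;
between-day variability (population SD of observed daily means) ≥ 5 mg/dL.
The variability gate exists because at constant glucose only the ratio
`K·g/(K·g + k_age)` is constrained — one number, two unknowns — and any
point on that ridge fits equally well; such sections are flagged
`insufficient_variability` rather than fitted.

## Identifiability and the precision limit

`k_age` is identified by the *lag* of HbA1c behind low-frequency glucose
variation; the HbA1c level itself only pins the ratio `K·g/k_age`. With
three laboratory draws, a subject near glycaemic steady state, and daily
mean glucose that is stationary with short memory, the second parameter
direction is weakly constrained: measured across synthetic subjects at the
default generator settings, the fit Jacobian's smaller singular value is
~2e-4–1.5e-3 (in residual-fraction per log-parameter), so laboratory assay
noise of 0.1 NGSP points (1e-3 in fraction) propagates to a lower bound of
tens to hundreds of days on the lifespan standard error. This is a property
of the data design, not the optimiser: noiseless fits recover the truth
exactly (median error 0.00 days over 50 subjects), while under 0.1-point
assay noise a large fraction of fits hit the lifespan bounds and the
converged remainder show a median error near 30 days. Cohorts whose
glycaemia trends over the observation window (therapy changes, seasonal
drift) are substantially better conditioned. Consumers should treat
per-subject lifespans from stationary-glucose cohorts as low-precision and
rely on the exclusion flags.

## Synthetic cohort generator

The generator emulates a six-month flash-monitoring study: readings every
15 minutes for 182 days, laboratory HbA1c at days 0/91/182.

Per subject: lifespan uniform on 60–150 days (inside the fitting bounds);
baseline glucose Normal(154, 25) mg/dL truncated at 80 (154 mg/dL is the
steady state of ~7% HbA1c at reference kinetics); `K` solved so the
steady-state HbA1c at baseline lands uniformly in 6–11% NGSP (a treated
diabetes population). Daily means follow a stationary AR(1) around the
baseline (coefficient 0.7, stationary SD 20 mg/dL — the identifiability
knob; set to 0 for negative tests). Within days, a circadian sinusoid
(amplitude 10 mg/dL), three post-meal excursions (log-normal amplitude,
median 40 mg/dL, peaking ~1 h after meals at 08:00/13:00/19:00) and i.i.d.
sensor noise (SD 5 mg/dL) are added and centred so the configured daily
mean is preserved exactly. The initial glycated fraction is the steady
state at the day-0 mean (a chronically stable patient). Laboratory values
are the model trajectory at visit days plus Normal assay noise (SD 0.1
NGSP points). Sensor-wear gaps are injected as invalid-reading windows.

Determinism: each subject's stream derives from `(seed, subject_index)` via
`numpy.random.SeedSequence`; identical config and seed reproduce cohorts
bit for bit.

What passing tests on this generator do **not** show about real data: the
generator commits the same daily-aggregation and constant-lifespan
assumptions as the estimator (an inverse crime), contains no sensor bias,
drift or calibration error, no hypoglycaemia dynamics, no within-person
lifespan variation, and — importantly — no glycaemic trend, which is the
regime where real cohorts carry more turnover information than this
generator does.

## Numerical choices and degenerate inputs

* Daily propagation is closed-form (cumulative products in log space); a
  six-month section loses at most ~e⁻⁶ of the start state, far from
  underflow.
* Quantiles (medians, IQRs) use linear interpolation between closest ranks.
* Adjustment-band boundaries are half-open upward: |Δ| bands [0,1), [1,2),
  [2,3), [3,∞) NGSP points.
* Traces must be strictly increasing in time; duplicate file timestamps are
  collapsed by mean before construction. Non-positive glucose, empty
  traces, out-of-range HbA1c fractions and non-positive rates raise typed
  errors; cohort drivers convert eligibility failures into flags, never
  crashes.
* Fit tolerances: `ftol` 1e-10, `xtol` 1e-8, `gtol` 1e-12.

## Problem sizes

Validation uses cohorts of 50 subjects × 182 days × 96 readings/day for
recovery studies (seconds per cohort) and 1000 random triples for the
steady-state equivalence identity; these sizes give sampling error well
below the asserted tolerances.
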