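# Methods

## Problem and pipeline

`emascan` quantifies time-varying within-person associations between
epoch-level accelerometer activity counts and EMA affect ratings. The
pipeline is: (1) align each EMA prompt to the epoch grid; (2) for a window
defined by a start offset ("location", minutes relative to the prompt,
negative = before) and a duration ("size"), compute a local moment of the
counts in the window; (3) fit a person-centered univariate multilevel model
of affect on that statistic; (4) repeat over a location × size grid and
control the false discovery rate over all cells.

## Window semantics

A window spans the half-open interval `[prompt + location, prompt + location
+ size)`. The prompt is floor-aligned to the epoch containing it, and both
location and size must be integer multiples of the epoch length, so a window
always contains exactly `size / epoch_length` epochs. Location −60 with size
10 is therefore the 10 minutes from 60 to 50 minutes before the prompt, and
positive locations probe activity *following* the prompt. Epochs outside the
recorded span come back as missing rather than raising, so edge prompts are
governed by the same coverage rule as wear gaps.

## Local statistics

Moments up to fourth order: arithmetic mean; sample SD (n−1); skewness as the
adjusted Fisher–Pearson G1 estimator; kurtosis as bias-adjusted excess (G2).
These match the defaults of common statistical software; the estimator
choice is not prescribed by the underlying methodology, so it is fixed here
and checked against direct formula evaluation in the tests. Moments are
undefined (window → missing) below their minimum n (1/2/3/4 respectively) or,
for the standardized moments, at zero variance.

Missing and non-wear epochs are *excluded* from the window before any
computation, never zero-filled — zero-filling would manufacture skewness in
count data. A window is missing when fewer than `min_coverage` (default 0.8,
a conventional actigraphy completeness threshold) of its expected epochs
survive.

Optional polynomial detrending removes slow diurnal structure before the
moment is taken: a least-squares polynomial (order configurable; order 2 is
a sensible default for ~2-h windows, order 1 for short ones) is fitted on
the epoch index and residuals replace the values. Detrending is per-window
by default; a per-calendar-day scope is available (`detrend_scope="day"`),
since day-level detrending is a defensible alternative reading of "removing
the diurnal trend". The constant term is always included, so residuals sum
to zero and the local mean of detrended data is degenerate by construction —
detrending is meant for SD/skewness/kurtosis.

## Multilevel models

The scan model per cell is the 2-level random-intercept model

    Y_tj = γ00 + γ10 (X_tj − X̄_j) + ζ0j + ε_tj.

Person-mean centering makes γ10 a purely within-person effect. Person means
are computed over the rows entering each specific fit (after listwise
deletion of missing outcomes/predictors), which keeps the within-subject
zero-sum identity exact in every fit. The general layer allows several
centered predictors, a between-subject predictor Z_j with cross-level
interaction terms Z·(X−X̄), random slopes, and a 3-level variant with
day-level random intercepts/slopes (observations in days in subjects).
In the 3-level model centering still uses the *subject* mean by default —
that is how the source model is written — with day-mean centering exposed as
an option (`centering="day"`).

Estimation is REML by default (ML available for likelihood-ratio work),
delegated to a standard Gaussian mixed-model fitter. Fixed-effect p-values
are two-sided Wald z; a between-within degrees-of-freedom t option exists
(`pvalues_t`). Optimizer failures are retried with gradient-free methods
(Powell, Nelder–Mead); a fit that still fails is returned flagged
`converged=False` rather than raising, so a 300-cell scan survives bad
cells, which become NA in every matrix.

Degenerate designs fail fast instead: a predictor constant within every
subject, fewer subjects than random-effect dimensions, or an all-missing
outcome raise typed errors before any optimizer runs.

## The scan and FDR

The default grid is 25 locations (−60…60, step 5 min) × 12 sizes (10…120,
step 10 min) = 300 cells. Each cell is fitted independently (univariate);
cells that cannot be fitted (coverage, insufficient subjects,
non-convergence) are NA and are *excluded from m* in the FDR computation —
imputing p = 1 would shift rejection thresholds arbitrarily. FDR control is
Benjamini–Hochberg step-up at q (default .05); Storey's π0-adaptive variant
(λ = 0.5) is available because the underlying method reference is ambiguous
between the two. Tests are two-sided: the matrices report signed slopes.

Serialized matrices put the smallest size in the top row and the most
negative location in the left column, so the top-left cell is the 10-min
window starting 60 min before the prompt. The scan is fully deterministic:
identical inputs yield bit-identical TSV output (numeric cells at 6
significant digits, `NA` sentinels).

## Synthetic studies

The generator produces a complete stated world for testing: per-subject
1-min gamma counts (shape 0.8, base scale 200 — right-skewed, occasional
zero epochs after rounding) modulated by a sinusoidal diurnal profile (±50%,
peak 14:00) and multiplicative bursts (Poisson arrivals at 0.5/h, 5× scale
for 5 min), emulating the nonnegative, positively skewed, bursty character
of real actigraphy. Prompts are anchored evenly through waking hours
(08:00–22:00, 6/day), jittered ±30 min, and dropped independently with
probability 0.2. Affect is drawn from the scan model itself with γ00 = 3,
γ10 = −0.5, var(ζ0) = 0.25, var(ε) = 0.5, using the centered 60-min local
mean starting at −60 min as the planted predictor, so the generative slope
has exactly the meaning the fit estimates (generation from the *raw*
predictor is an option for studying centering mismatch). Prompts whose
planted window fails coverage are dropped. All randomness flows from one
seed through per-subject spawned generator streams (activity / schedule /
affect), so subject j's data are invariant to cohort size.

What the generator does **not** emulate: sleep architecture and true
non-wear, weekday/weekend structure, power-law distributions of rest/active
bouts (the burst process is a pragmatic stand-in), floor/ceiling effects and
discreteness of affect scales, and informative missingness. A green
simulation test therefore establishes statistical correctness of the
estimator and scan machinery under the stated world, not realism of any
particular empirical dataset — the original 9-participant illustration of
this method is not reproducible (no deposited data), so tests are structural
constants, analytic oracles and parameter-recovery/calibration simulations.

## Numerical choices

- Epoch alignment: half-open intervals with floor alignment; a 1e-9-minute
  tolerance absorbs timestamp rounding.
- Detrending uses a numerically stable polynomial least-squares fit on the
  raw index axis; windows are ≤ 120 points and order ≤ 3 in practice, well
  within safe conditioning.
- Variance components are reported clamped at ≥ 0 (REML can return exact
  boundary zeros).
- Grid construction validates that steps divide their ranges exactly
  (1e-9 tolerance) instead of silently truncating.
- BH step-up uses a stable sort, making ties and hence the whole scan
  deterministic.

## Known limitations

Gaussian outcomes only (no ordinal/Poisson affect models); no autoregressive
residual structure within days; no Satterthwaite/Kenward–Roger degrees of
freedom (small-cohort Wald z p-values can be mildly anti-conservative — the
null-calibration test runs at 20 subjects where calibration is adequate);
the scan fits cells independently and does not model the strong spatial
correlation between overlapping windows beyond FDR control.
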