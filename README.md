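# emascan

Window-scan analysis of the within-person coupling between
accelerometer-measured physical activity and momentary affect reported by
ecological momentary assessment (EMA).

Intensive-longitudinal studies pair a wrist accelerometer (activity counts
accumulated to 1-min epochs) with several affect prompts per day. A central
analytic question is *which* window of activity — how long, and where in time
relative to the prompt — carries the association with affect. `emascan`
answers it by brute force over a grid of windows: for every window location
and size it computes a local moment of activity around each prompt, fits a
person-centered multilevel model, and controls the false discovery rate over
the resulting coefficient matrix.

It is written for EMA/actigraphy methodologists and analysts who want the
scan as a library (pandas in, results objects out) or as a command-line tool.

## The model

For each grid cell, the local statistic `X_tj` (mean, SD, skewness or excess
kurtosis of the counts in the window `[prompt + location, prompt + location
+ size)`, optionally polynomially detrended) enters the univariate
random-intercept model

    Y_tj = γ00 + γ10 (X_tj − X̄_j) + ζ0j + ε_tj,

where `Y_tj` is subject *j*'s affect at prompt *t*, `X̄_j` is the subject's
own mean of the predictor (person-mean centering, so γ10 is a *within-person*
effect), `ζ0j ~ N(0, τ²)` is a subject random intercept and `ε_tj ~ N(0, σ²)`
the momentary residual. Estimation is REML via a Gaussian linear mixed model;
inference on γ10 uses Wald z statistics. The scan's default grid is 25
locations (−60…+60 min in 5-min steps) × 12 sizes (10…120 min in 10-min
steps) = 300 cells; the 300 p-values are adjusted by the Benjamini–Hochberg
step-up procedure at q = .05.

The general modelling layer (`emascan.mlm`) also supports multiple centered
within-person predictors, a between-subject predictor with cross-level
interactions, random slopes, ML estimation, and a 3-level variant
(observations in days in subjects) with day-level random intercepts/slopes.

## Worked example

```python
from emascan import (LocalStatConfig, SyntheticConfig, default_grid,
                     run_scan, simulate_study)

study = simulate_study(SyntheticConfig(seed=1))   # 9 subjects, 7 days
result = run_scan(study.activity, study.ema, grid=default_grid(),
                  config=LocalStatConfig(statistic="mean"), q=0.05)
print(f"subjects: {len(study.activity)}  prompts: {len(study.ema)}")
print(result.summary())
```

prints

```
subjects: 9  prompts: 298
Window scan of local mean
Grid: 25 locations x 12 sizes = 300 cells (300 fitted, 0 failed)
FDR (bh) at q=0.05: 294 significant cells
Largest |slope| -0.5123 at location -60 min, size 70 min (p=0)
```

The synthetic study plants a slope of −0.5 of affect on the centered 60-min
local activity mean starting 60 min before each prompt; the scan recovers a
negative, FDR-significant coefficient almost everywhere (windows overlap
heavily), with the largest magnitude at a window overlapping the planted one.
`result.to_tsv(prefix)` writes the slope, p-value and significance matrices
as TSV (rows = sizes, smallest on top; columns = locations ascending);
`result.plot()` draws the significance-masked coefficient heatmap.

The same from the shell:

```bash
emascan simulate --seed 1 --out study/
emascan scan --activity study/activity.csv --ema study/ema.csv \
    --stat mean --loc -60:60:5 --size 10:120:10 --q 0.05 --out study/scan
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` simulates the
default 9-subject study from the given seed, runs the full 300-cell scan of
the local mean with BH-FDR at q = .05, writes the three scan matrices next to
the output path, prints the scan summary, and writes the JSON manifest to
`--out`.
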