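# relapsim

Mechanistic simulation and hazard-rate analysis of post-surgery
breast-cancer relapse.

## The problem

Relapse hazard after mastectomy is not a smooth, slowly varying curve.
In high-quality series of untreated patients, the discrete hazard of
recurrence — events per 3-month interval divided by patients still at
risk — shows a *trimodal* structure: a sharp peak near 10 months, a
second peak near 30 months, and a broad late peak at 50–60 months,
followed by small wiggles that are noise.  The early peaks are too sharp
to come from any purely stochastic progression process; they look
synchronized to the surgery itself.  A mechanistic reading is:

- **~10-month peak** — avascular micrometastases, held dormant at their
  diffusion-limited size, undergo an *angiogenic switch* at surgery and
  grow to clinical detection;
- **~30-month peak** — dormant single cells are induced into division at
  surgery, grow to the avascular limit, and then switch stochastically;
- **50–60-month peak** — natural-history progression uncoupled from
  surgery (surgery only stops further seeding from the primary);
- a **cured fraction** that never relapses.

`relapsim` implements this four-group mixture as a forward simulator and
couples it to the survival-analysis pipeline needed to see (or reject)
such structure in right-censored data: life-table hazard at configurable
bin width, Kaplan-Meier curves, Epanechnikov kernel smoothing,
prominence-based peak detection with a cross-modality / patient-subset
robustness screen, and least-squares calibration of the group weights
against target hazard or disease-free-survival (DFS) curves.

## The model

Deposit growth is Gompertzian,

    N(t) = N_inf · exp( ln(N0 / N_inf) · e^(−a·t) ),

with cells-scale anchors `N_inf = 1e12`, avascular limit `1e5`, clinical
detection `1e9`, and a per-deposit rate `a` drawn log-symmetrically
around a median chosen so that a newly vascularized avascular deposit
reaches detection in 10 months.  Angiogenic-switch and dormancy-exit
waiting times are gamma distributed (shape = number of latent
progression stages, shape 1 = exponential).  A cohort is a weighted
mixture of the four groups; observation is administratively censored at
120 months.

The discrete hazard in bin *j* of width *w* is
`h_j = d_j / n_j` (events in `[e_j, e_j+w)` over subjects with time
`≥ e_j`), the quantity whose fine structure carries the biology: visible
at 3-month bins, gone at 12-month bins.

## Worked example

```python
import numpy as np
import relapsim as rs

config = rs.default_config(n_patients=10000, seed=1)
records = rs.simulate_cohort(config)
data = rs.SurvivalDataset.from_records(records)

binned = rs.discrete_hazard(data, bin_width=3.0)
smoothed = rs.kernel_smooth(binned)          # bandwidth = 6 months
peaks = rs.find_peaks(smoothed)
print("peak times (months):", peaks.peak_times)
print("peak heights (per 3-month interval):", np.round(peaks.peak_heights, 4))

km = rs.km_curve(data)
print("DFS at 5 and 10 years:", np.round(km([60.0, 120.0]), 3))

report = rs.robustness_scan(data, bin_widths=(3.0,), bandwidths=(4.5, 6.0, 9.0))
print("stable peaks (months):", np.round(report.stable_peaks, 1))
```

prints

```
peak times (months): [10.5 31.5 55.5]
peak heights (per 3-month interval): [0.0566 0.029  0.0292]
DFS at 5 and 10 years: [0.576 0.498]
stable peaks (months): [10.5 30.2 57. ]
```

The three detected maxima are the two surgery-triggered modes (10 and
~30 months) and the broad natural-history mode (~55 months); about half
the cohort is cured, so 10-year DFS sits near 0.50.  The robustness scan
re-detects peaks across bandwidths, a piecewise-exponential modality and
disjoint patient halves, and only locations supported by at least 75% of
settings are reported stable.

The same pipeline is scriptable from the shell:

```
relapsim simulate --seed 1 --n-patients 10000 --out cohort.csv
relapsim hazard cohort.csv --bin-width 3 --out hazard.csv
relapsim peaks cohort.csv --out peaks.csv
relapsim run --seed 1 --outdir results/        # end-to-end with manifest
relapsim calibrate --target dfs.csv --out fit.csv
```

Scenario constructors `high_risk_config()` (no cured fraction, triggered
groups dominant: ~90% of relapses within 48 months) and
`node_negative_config()` (80% cured: 10-year DFS ≈ 80%) encode the
published qualitative splits for the extreme prognostic categories, and
`nsaid_scenario(config, suppression)` down-weights the two
surgery-triggered groups to emulate a perioperative anti-inflammatory
intervention.

The `synthetic` module generates cohorts from an *explicit* cure +
lognormal-component mixture with a closed-form population hazard
(`truth_hazard`), so every estimation stage can be validated against
ground truth independently of the mechanistic simulator.

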