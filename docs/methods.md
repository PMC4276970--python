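# Methods

## Growth law

Metastatic deposits grow deterministically by the Gompertz law
`N(t) = N_inf · exp(ln(N0/N_inf) · e^(−a·t))` with asymptote
`N_inf = 1e12` cells.  Three size anchors are order-of-magnitude
conventions from the breast-cancer kinetics literature, all configurable
in `SimConfig`:

| parameter        | default | meaning                                   |
|------------------|---------|-------------------------------------------|
| `avascular_limit`| 1e5     | diffusion-limited dormant plateau (cells) |
| `detection_size` | 1e9     | clinical detection, ~1 cm³ (cells)        |
| `n_inf`          | 1e12    | growth asymptote (cells)                  |

The median Gompertz rate is not free: it is fixed at
`a* = 0.0847298.../month`, the unique rate for which growth from the
avascular limit to detection takes exactly 10 months, anchoring the
first relapse mode.  Per-deposit heterogeneity multiplies `a*` by
`exp(sigma_log · Z)`, `Z ~ N(0,1)`, with `sigma_log = 0.3`.  This
log-symmetric spread is the single parameter producing peak width; the
original stochastic-growth formulation it replaces perturbed growth with
unspecified random kicks, which are not recoverable and would add
parameters without adding testability.  `sigma_log = 0` makes the
simulator fully deterministic given group assignment, which the tests
exploit as an oracle (every triggered-avascular relapse at exactly 10.0
months).

## The four-group mixture

One fate-determining deposit is simulated per non-cured patient; deposit
multiplicity is absorbed into group weights, since only the earliest
detection is observable.  Waiting times are gamma distributed with
integer shape ("latent progression stages"); shape 1 is an exponential.
A single exponential switch wait cannot place a density mode away from
its origin — a shifted exponential peaks at its shift — so the
30-month and 50–60-month modes require shape > 1.  The shipped defaults
(calibrated once, by simulation, to put the smoothed-hazard modes at
10 / ~30 / ~55 months, and not revisited):

| group               | weight | waits (shape, mean months)                |
|---------------------|--------|-------------------------------------------|
| TRIGGERED_AVASCULAR | 0.18   | none: switch at surgery, 10 mo growth      |
| TRIGGERED_SINGLE    | 0.15   | switch gamma(5, 13.5) after 6.36 mo growth |
| NATURAL_HISTORY     | 0.17   | exit gamma(8, 21) + switch gamma(8, 21)    |
| CURED               | 0.50   | censored at horizon                        |

Whether the late mode is "temporally tied" to surgery is left open by
the biology; here its clock starts at t = 0 only because surgery stops
further seeding — both readings are expressible through
`rate_exit_dormancy` / `exit_shape`.

Scenario configs reuse the same timing parameters and change only
weights: `high_risk_config` (0.60 / 0.29 / 0.11 / 0.0) reproduces the
"all relapse, ~90% early" description of the worst prognostic category;
`node_negative_config` (0.05 / 0.05 / 0.10 / 0.80) reproduces "surgery
alone cures 80%, relapsers split half early / half late".
`nsaid_scenario(config, s)` multiplies the two triggered-group weights
by `1 − s` and moves the removed mass to CURED, leaving timing
untouched.

Censoring is administrative at `horizon = 120` months; optional
independent exponential censoring (`censor_rate`) exists for estimator
robustness tests.  Pre-surgery seeding times are not modeled — they are
unobservable at 3-month resolution.

## Estimators

- **Life-table hazard**: `h_j = d_j / n_j` on half-open bins
  `[e_j, e_j + w)`, with `n_j` = subjects with observed time `≥ e_j`
  (simple convention; `actuarial=True` half-weights within-bin
  censorings).  Time 0 is surgery.  Empty-risk-set bins are NaN-flagged,
  never 0.  Hazard is reported as per-interval conditional probability;
  `hazard_to_rate` converts to per-month rates.
- **Kaplan-Meier**: delegated to `lifelines.KaplanMeierFitter` (ties:
  events before censorings), wrapped as a right-continuous step
  function.
- **Kernel smoothing**: discrete Nadaraya-Watson with an Epanechnikov
  kernel on the bin-center grid, reflection padding at both boundaries.
  Constants are reproduced exactly everywhere and interior spike mass is
  conserved to 1e-9, so smoothing cannot manufacture or destroy overall
  hazard mass.  Default bandwidth 2× bin width; a bandwidth below the
  bin width warns and passes data through.  The paper trail behind this
  choice is thin everywhere in this literature — bandwidth is therefore
  an explicit argument in every API.
- **Piecewise exponential**: closed-form MLE (events / person-time per
  segment) with the log-likelihood reported; cross-checked in the tests
  against `lifelines.PiecewiseExponentialFitter`.

## Peak detection and robustness

`find_peaks` is purely geometric: interior local maxima with scipy
prominence at least `min_prominence_frac` (default 0.1) of the curve
maximum; endpoints are never peaks; detection is deterministic.

`robustness_scan` implements the constancy criterion for "true" peaks
along two axes: (a) smoothing modality — bin widths × bandwidths for the
kernel smoother, plus the piecewise-exponential rate profile per bin
width; (b) patient subsets — every modality is re-run on `n_subsets = 2`
disjoint random halves of the cohort.  Axis (b) is essential: all
re-smoothings of the same events share their sampling noise, so a noise
bump that clears the prominence threshold once tends to clear it in
every setting; disjoint subsets are the within-dataset analogue of
"different databases and different subsets of patients".  Within each
setting, peaks whose prominence is below `noise_z = 3.5` sampling
standard errors of the smoothed estimate are discarded (binomial
variance propagated through the kernel weights; `rate/√events` for the
piecewise modality) — small late-time hills carried by few events are
noise by construction.  A location supported (within `match_tol = 4.5`
months) by at least `stability_frac = 75%` of all settings is stable;
candidate locations are actual detected peaks, and matching is
bounded-width, so scattered noise cannot chain into a wide pseudo-peak.
`noise_z` was set from the measured separation between noise-peak and
true-peak prominence/SE ratios (noise ≲ 4.5, true modes ≳ 5 at half
samples of n = 10,000 cohorts) before the acceptance suite was frozen.

## Calibration

`fit_mixture` searches group weights on the probability simplex via a
softmax reparameterization with Nelder-Mead.  Common random numbers: a
conditional relapse time is pre-drawn for *every* patient under *every*
group from seed-derived substreams, so candidate weights only move
assignment thresholds over fixed uniforms and the loss surface is
deterministic and nearly smooth in the weights.  The loss is a weighted
least-squares sum over target hazard bins (inverse-variance weights from
the target's own life table when risk-set counts are available, with a
continuity-corrected variance so empty bins get finite weight) plus
squared DFS residuals, blocks weighted 1:1 by default.  The default
Nelder-Mead perturbation around a zero start is smaller than the
finite-cohort loss granularity (1/n_sim), so an explicit initial simplex
with 0.5-logit steps is supplied.  Timing parameters (`median_a`,
`sigma_log`, group rates) are fixed by default and freeable by name —
mirroring a weights-only calibration exercise.  Non-convergence flags
the result rather than raising.  Recovery of known weights is better
than ±0.015 at `n_sim = 20,000` in the test conditions (tolerance
±0.05).

## Synthetic ground truth

`synthetic.generate` draws from an explicit mixture — cure fraction plus
lognormal relapse components `(weight, median location, log-spread)` —
independent of the mechanistic simulator, with closed-form population
hazard `truth_hazard` (left-limit CDF convention so point masses land in
the half-open bin containing them).  The default spec (cure 0.50,
components 0.18@10, 0.17@30, 0.15@55 months, spreads 0.30/0.22/0.15,
horizon 120) emulates an untreated premenopausal-like cohort: trimodal,
over half of relapses early.  What passing tests on it show: the
estimation pipeline recovers known multimodal structure at realistic
cohort sizes.  What they do not show: anything about real registry
artifacts — cause-of-death misclassification, time-to-event rounding,
loss to follow-up, covariate mixtures — none of which are emulated.

## Problem sizes and numerics

Simulated cohorts in tests and acceptance runs use n = 10,000–50,000
patients (calibration at n_sim = 20,000 over 10 seeds), sizes at which
every Monte-Carlo comparison in the suite resolves its tolerance with
3–4σ margins while the whole suite stays interactive.  All randomness
flows from explicit integer seeds through `numpy` `SeedSequence`
substreams; cohorts are byte-reproducible.  Degenerate inputs are
defined, not special-cased away: `sigma_log = 0` gives deterministic
kinetics, `rate = 0` means the transition never fires (censored),
`rate = inf` fires instantly, a point-mass synthetic component gives a
unit hazard bin.

## Config file schema (YAML, `schema_version: 1`)

```yaml
schema_version: 1
n_patients: 10000
horizon: 120.0
seed: 0
censor_rate: 0.0
growth: {median_a: 0.08472978603872036, sigma_log: 0.3}
thresholds: {avascular_limit: 1.0e+05, detection_size: 1.0e+09, n_inf: 1.0e+12}
groups:
  TRIGGERED_AVASCULAR: {weight: 0.18}
  TRIGGERED_SINGLE: {weight: 0.15, rate_switch: 0.37037, switch_shape: 5}
  NATURAL_HISTORY: {weight: 0.17, rate_exit_dormancy: 0.380952, exit_shape: 8,
                    rate_switch: 0.380952, switch_shape: 8}
  CURED: {weight: 0.5}
```

Readers reject newer schema versions; survival CSVs are
`patient_id, time_months, event[, group]` with positive float months and
0/1 events; target CSVs are either `(bin_start, bin_end, hazard[, n_at_risk])`
or `(time_months, dfs)`.

## Known limitations

- Group weights, not deposit counts, carry all multiplicity; there is no
  per-patient seeding model.
- The late-mode timing parameters are calibrated defaults, not estimates
  from data; real late-relapse kinetics may be wider or shifted.
- No covariates, no adjuvant-therapy effect model, no mortality
  endpoint (relapse only): treated cohorts and all-cause hazards are out
  of scope.
- Cross-database peak constancy cannot be checked without data; the
  subset axis of `robustness_scan` is its within-dataset surrogate.
- Digitized literature curves can be supplied as calibration targets,
  but digitization itself is outside the package.
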