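# Methods

## Sleep metrics from epoch data

Each device scores a night as an ordered sequence of 30 s or 60 s epochs,
each sleep (`S`) or wake (`W`). Epoch timestamps denote the epoch *start*
and epochs are half-open `[start, start + len)`; only epochs whose start
lies in `[bedtime, risetime)` are considered, and they must tile that
window exactly. Sleep onset is the start of the first sleep epoch; sleep
offset is the *end boundary* of the last sleep epoch — one minute after its
start at 60 s epochs, 30 s after at 30 s epochs. With these conventions the
seven per-night summaries (TIB, onset, offset, onset latency `S`, offset
latency, duration `D`, TST `T`) are integer multiples of the epoch length
(reported in hours) and satisfy `TIB = S + D + offset latency` exactly.
Nights with no sleep epoch, inverted markers or gappy series are flagged
(`no_sleep_epoch`, `marker_order`, `series_gap`) and excluded from all
downstream analysis. Both devices' series are summarized by the same
counting rule; the package does not emulate any vendor's proprietary
onset/offset heuristics.

## Agreement

Nights are pooled across participants into an n × 2 ratings matrix (row =
night, column = device); within-participant clustering is deliberately
ignored, mirroring how small validation studies analyze such data, and is
listed under limitations. From the two-way crossed ANOVA without
replication (MSR between nights, MSC between devices, MSE residual):

- consistency ICC `(MSR − MSE) / (MSR + (k−1) MSE)` — blind to a constant
  device offset;
- absolute-agreement ICC
  `(MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE))` — penalizes it.

95% CIs use the exact F interval (`F = MSR/MSE`) for the consistency form
and the Satterthwaite-approximated F interval for the absolute form, the
McGraw & Wong formulation implemented by the common ICC packages; the
absolute lower bound can be negative. The test suite checks both forms
against a definition-level sum-of-squares oracle (1e-10), against
`pingouin` on shared fixtures (estimates to 1e-6, CIs to that package's
printed precision), and verifies 93–97% empirical CI coverage over 500
simulated 64 × 2 matrices with true absolute ICC 0.7 (variance components
0.7 / 0.05 / 0.25). Degenerate inputs (n < 3, missing cells, zero
denominator) raise rather than return NaN. Perfect agreement returns
estimate and CI of exactly 1.

Bland–Altman summaries use `test − ref` throughout (negative = the test
device underestimates); limits of agreement are mean ± 1.96 SD (SD with
n−1). ICC labels follow the usual bands: < 0.5 poor, 0.5–0.75 moderate,
0.75–0.9 good, ≥ 0.9 excellent, applied to point estimates.

## Calibration

Stage 1 (duration): OLS of reference onset latency on test latency,
`L̂ = αS + β`, with α constrained to [0, 1] — the latency correction can
neither be negative nor exceed the measured latency; if the unconstrained
slope falls outside (possible when reference latencies are noisy and
heavily floor-clipped) it is clamped and the intercept re-derived for the
clamped slope. The provisional correction `D* = D + (S − L̂)` is then
shifted by a bias term `b` selected by exhaustive grid search over ±5 min
in 0.1 min steps, maximizing the absolute-agreement ICC of
`min{D* + b, TIB}` against the reference duration; the clip is inside the
objective so the search optimizes the final equation. Ties (within 1e-12)
break toward smaller |b|, then negative b — a deterministic rule. The model
stores the composite coefficients `c = 1 − α`, `d = −β + b*` (the α, β, b*
parts live in the fit diagnostics together with per-stage RMSE).

Stage 2 (TST): OLS of reference TST on test TST over *all* nights
(including nights whose duration was clipped), applied as
`T′ = min{m·T + t₀, D′}` with an additional floor at 0 that only pathological
user-supplied models can trigger. Duration is always calibrated before TST
so the TST clip bound is the calibrated duration. The regression direction
is reference-on-test in both stages (the test device is being calibrated
toward the reference). The clipping contracts `D′ ≤ TIB` and
`0 ≤ T′ ≤ D′` hold for every night under every model.

The built-in default model carries the published iAide2→MW8 coefficients
(0.59, 0.26, 0.73, 2.15).

## Synthetic cohort generator

The generator emulates a small free-living dual-actigraph validation
study. Participant counts and nights (6 participants, 5–21 nights each,
capped to 64 total by decrementing the largest draws) match that design.
Per night, in hours:

| parameter | default | rationale |
|---|---|---|
| TIB | Normal(6.9, 0.7), truncated [5, 10], whole minutes | plausible adult TIB; level chosen jointly with WASO so both device biases land at study-reported values |
| test onset latency `S` | 0.65 + Gamma(shape 2, mean 0.41) | the test device's large latency overestimate; the 0.65 h shift keeps the noise-free reference latency `0.41·S − 0.26` nonnegative, so zero-noise OLS recovery is exact |
| reference latency | `0.41·S − 0.26 + N(0, 0.15)`, clipped to [0, TIB] | inverse of the duration calibration: `1 − 0.59 = 0.41`, `−0.26` |
| offset latencies | Exponential, mean 0.03 (test) / 0.005 (ref) | near-zero offset-latency bias |
| reference WASO | Poisson interruptions at 2.8/h of sleep, geometric episodes of mean 2.5 min | intra-sleep wake; no published description exists, so this is a modeling choice |
| test TST | `(ref TST − 2.15 − N(0, 0.40)) / 0.73` | inverts the TST calibration so OLS fitting recovers 0.73/2.15 as noise → 0 |

Latent times are floored onto each device's epoch grid when the state
sequences are realized (wake episodes are placed uniformly within the
sleep-window interior, never at its edges). Derived metrics therefore match
the latent quantities only up to quantization: latencies and TST within one
epoch, duration — which combines two floored boundaries — within two.
Because of this, every generated record also carries its latent truth, and
the exact-recovery tests (zero noise, 1e-6–1e-8) fit on latent metrics;
epoch-derived fits are tested at realistic tolerances (±0.05 on slopes,
±0.08/±0.15 h on intercepts at low noise). Infeasible draws (negative
durations, TST targets exceeding the test sleep window, unplaceable wake
epochs) are redrawn per night up to a bounded retry budget, then fail with
a diagnostic. A single seeded `numpy` Generator drives everything, so equal
configs give byte-identical cohorts.

With the defaults the cohort reproduces the studied error structure's
headline biases — uncalibrated mean differences ≈ −0.86 h (duration) and
≈ −0.9 h (TST), test offset-latency mean ≈ 0.03 h — and calibration raises
the absolute-agreement ICC for both measures in every seed we tested, with
post-calibration mean differences within ±0.01 h.

What the generator does **not** emulate, and what passing tests therefore
do not show about real data:

- no participant-level heterogeneity (all nights are exchangeable draws),
  so between-participant variance and clustering effects are absent — this
  is also why the leave-one-out ranges here are narrower than a real
  cohort's;
- night-to-night spread of the device disagreement is smaller than real
  validations report, so uncalibrated consistency ICCs run high
  (≈ 0.97 vs ≈ 0.9 for duration);
- at the default noise levels the *fitted* coefficients deviate from the
  generating 0.59/0.73 by design: the TST inversion puts the noise in the
  regressor, so reference-on-test OLS is attenuated (errors-in-variables).
  Recovery is asserted only in the low-noise limit, where the effect
  vanishes;
- no naps, no multi-bout sleep, no circadian drift, no missing epochs, and
  sleep/wake states are taken as given — no raw accelerometry scoring.

## Sensitivity analysis

Leave-one-participant-out, two modes: *fixed* applies one full-cohort
model to every subset; *refit* refits both calibration stages (including
the bias grid search) per subset. For each exclusion the absolute-agreement
ICCs of calibrated duration and TST are recorded, and min–max ranges are
collected over valid subsets; degenerate subsets are reported as invalid
entries, never silently dropped. The procedure is deterministic. The range
is not asserted to contain the full-cohort ICC (that is not mathematically
guaranteed).

## Problem sizes and numerical choices

The test suite and acceptance script work at the study's own scale (64
nights) and complete in well under a minute: 100 seeded cohorts for the
improvement check, 500 replicates for CI coverage, ≥ 1000 fuzzed nights
for the clipping bounds, 20 seeds for leave-one-out stability, and one
n = 640 cohort for consistency of parameter recovery. Floating-point
policy: epoch flooring uses a 1e-9 guard for exact grid points; ICC oracle
agreement is asserted at 1e-10; grid-search ICC ties at 1e-12; OLS is by
`numpy.linalg.lstsq`. All durations are held in hours internally; CSVs
round to 4 decimals (0.36 s), below epoch resolution.

## Known limitations

Pooling nights ignores within-participant correlation, so ICC confidence
intervals are anti-conservative for clustered data; the calibration is
linear and cohort-level (no per-participant random effects); calibrated
onset/offset *timestamps* are not produced, only durations; and k > 2
devices, while supported by the ANOVA formulas, are not exposed in the
pipeline.
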