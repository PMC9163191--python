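# Methods

This note documents the models, numerical choices and limitations of the
package; it is the place where genuinely open design decisions are
recorded. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

Raw input is tri-axial wrist acceleration in units of g at a nominal 30 Hz.
The activity measure is the Euclidean norm of the *change* in the
acceleration vector between consecutive samples, which removes gravity and
is therefore orientation-invariant. The norm (converted to mm/s², 1 g =
9 806.65 mm/s²) is smoothed with a centred rolling Gaussian window spanning
30 samples; the window fixes the support, not the width, so σ = window/6
puts ±3σ at the window edges. Edges are handled by reflection padding to
avoid onset transients. The high-pass step is implemented as noise-floor
*gating* — samples below the threshold (default 20 mg = 196.133 mm/s²) are
zeroed, not subtracted — consistent with suppressing sensor noise while
leaving genuine movement magnitudes untouched; whether the sum should be
taken before or after gating is not decidable from the design being
reproduced, and gating-then-summing is adopted. The first difference
consumes one sample, after which whole 1-min epochs (rate × 60 samples) are
summed and any trailing partial epoch is dropped.

## Quality control

Recordings are cropped between their first and last midnight (local clock
as encoded in the file; no timezone conversion) to a whole number of 24-h
days. A recording is rejected if any of the following fire: MADRS > 40;
fewer than 5 whole days retained; an operator shift-work annotation is
present (shift work is deliberately *not* auto-detected — it was a visual
screening judgement, so it enters as an annotation); any contiguous gap
longer than 120 epochs (2 h). Gaps of up to 2 h are imputed with the mean
daily-profile value at the same clock minute, computed from unmasked
epochs, and stay flagged in the gap mask. Imputation is required because
DFA and IV need a contiguous series; profile imputation is neutral for IS
(it pulls toward the daily mean) and mildly smoothing for IV/DFA over at
most 2 h — an accepted, documented bias.

## Features

* **Daily profile** — per-clock-minute mean across days, masked epochs
  excluded.
* **M10/L5/RA** — exhaustive search over all 1440 circularly wrapped
  windows (600 and 300 min) on the mean daily profile; values are reported
  per hour (mean counts/min × 60), locations are window midpoints in clock
  hours, ties break to the earliest window start. Computing on the mean
  profile (rather than per day, then averaging) matches the convention in
  which the reported locations are single clock times.
* **Circadian period** — Lomb–Scargle periodogram (scipy implementation;
  equivalent to a per-frequency least-squares sinusoid fit of the centred
  series) on a frequency grid with spacing 1/(T·ofac), ofac = 10,
  restricted to a 20–28 h band so that ultradian harmonics cannot win the
  argmax. Masked epochs are simply omitted — the estimator handles uneven
  sampling natively.
* **DFA** — DFA-1: integrate the mean-centred series, split into
  non-overlapping boxes, remove a per-box linear trend, F(n) = RMS residual;
  50 log-spaced candidate box sizes between 4 and 1440 samples,
  deduplicated to integers, boxes larger than length/4 dropped. α_full is
  the slope of log F over all boxes; the short/long sub-ranges default to
  4–90 min and 120–1440 min — the crossover placement (~1.5–2 h) follows
  common practice in the DFA literature on activity series and is
  configurable, since "short" and "long" are not otherwise pinned down.
* **IV/IS** — on non-overlapping bin means (5/30/60 min; masked epochs
  excluded from bin means, trailing partial bins dropped):
  IV = n·Σ(xᵢ−xᵢ₋₁)²/[(n−1)·Σ(xᵢ−x̄)²], ≈2 for uncorrelated bins;
  IS = n·Σₕ(x̄ₕ−x̄)²/[p·Σᵢ(xᵢ−x̄)²], 1 for perfectly repeating days,
  ≈1/n_days for structureless data. Both are affine-invariant, so they are
  comparable across devices; M10/L5 are not, which is why the model space
  emphasises shape features.
* Sex is carried for descriptive tables only; the 16-predictor model space
  is {age, period, M10, M10L, L5, L5L, RA, α_full, α_short, α_long, IV5,
  IV30, IV60, IS5, IS30, IS60} — exactly the continuous candidates whose
  1–6-subsets number 14,892.

## Model development

Ordinary least squares throughout (no regularisation, no cross-validation).
RMSE always uses the plain mean-squared-residual denominator so train and
test accuracies are directly comparable. Standardized coefficient j is
bⱼ·sd(xⱼ)/sd(y). VIFⱼ = 1/(1−R²ⱼ) from regressing predictor j on the rest;
single-predictor models have VIF 1; perfect collinearity reports +inf. The
internal filter applies three *strict* inequalities: every VIF < 5,
R² > 0.5, RMSE < 3.

Forward-stepwise selection starts from the intercept-only model and adds,
per step, the candidate with the smallest partial-F p-value (entry
threshold p < 0.05, a conventional default exposed in config) or the
largest AIC decrease (strict). Ties break on feature order. Restriction
cells (e.g. excluding age and/or period) and both criteria can be run as a
grid from the pipeline config.

External validation freezes the training coefficients and requires Pearson
r above the two-sided α = 0.05 critical value r = t/√(t²+n−2) — recomputed
from the actual test-set size rather than hard-coded, 0.576 being the
n = 12 case — and test RMSE < 3. Zero-variance predictions leave r
undefined and fail with a flag. Two baselines calibrate achieved accuracy:
the dummy model (constant test-mean prediction; its RMSE equals the
population SD of the test scores) and an empirical RMSE distribution over
random integer predictions drawn uniformly in the observed test min–max
(inclusive; configurable), reported as P(RMSE ≤ x).

## Synthetic data

The generator emulates the *class* of signal the analysis consumes, not any
particular device: per 1-min epoch,

    x(t) = max(0, [profile(t) + noise_sd·(profile(t)/mesor)·ξ_α(t)] · j(day))

where profile(t) = mesor + amplitude·cos(2π(t − acrophase)/period) is the
circadian mean, ξ_α is zero-mean unit-variance long-range-correlated noise
produced by spectral synthesis (amplitudes ∝ f^(−β/2), β = 2α − 1, random
phases — simple, seedable and analytically characterised), and j(day) is a
per-day factor 1 + N(0, day_jitter_sd) (floored at 0). Three deliberate
modelling choices:

* the noise is **amplitude-modulated by the profile** — still nights,
  bursty days. With homoscedastic noise, any level strong enough to give
  realistic fragmentation (IV5 ≥ 0.35) floods the night trough and
  collapses the relative amplitude; modulation resolves the conflict and
  matches how wrist activity actually behaves;
* the day factor multiplies the **whole day's signal**, so active days are
  active throughout — this is what makes interdaily stability fall as the
  jitter grows;
* rectification at zero (not absolute value) reproduces the zero-inflated
  nights of real recordings.

Defaults (mesor 60, amplitude 50 counts/min, acrophase 15 h, α = 1.0,
noise_sd 600, day_jitter_sd 0.2, 7 days) were calibrated once, by grid
search, so that the extracted battery falls inside the ranges observed in
real depressed-patient cohorts (period ≈ 23.5–25.4 h, IV5 ≈ 0.35–0.68,
IS5 ≈ 0.19–0.44, RA ≈ 0.65–0.96, α ≈ 1), and so that the recording-level
DFA exponent tracks the target α within ±0.15 over targets 0.7–1.3. The
count scale itself is arbitrary (devices differ); all shape features are
scale-invariant.

Cohorts perturb the template per subject — lognormal (sd 10%) on mesor and
amplitude, additive N(0, 0.03) on the target DFA exponent, lognormal
(sd 20%) on noise scale and day jitter — so subjects span genuinely
different rhythm phenotypes with feature dispersions comparable to real
cohorts, rather than resampled copies of one subject. MADRS is then
intercept + Σ coefficient·feature + N(0, noise_sd), rounded to integer and
clipped (default 18–40; rounding and clipping can be disabled for exact
algebraic recovery tests). Note that in this generator α_full and IV5 are
strongly negatively correlated across subjects (both are driven by the
noise spectrum), so recovery experiments use the near-orthogonal
(α_full, IS5) pair as ground truth.

What the generator does **not** emulate: raw 30 Hz biomechanics (the raw
fixture is gravity plus noise bursts, for pipeline plumbing only),
shift-work or treatment trends, naps/weekend structure, device-specific
count nonlinearity. Passing tests therefore demonstrate correctness of the
estimators and of the selection/validation machinery under a controlled
generative model — not clinical validity on real patients.

## Problem sizes and determinism

Simulated studies use cohorts of 12 subjects with 7-day recordings
(matching the design being reproduced), 40-subject cohorts for recovery
experiments, and 10⁵ draws for the random-prediction null (its quantiles
are stable to <0.01 against larger runs, as the suite checks). Every
stochastic stage takes an explicit seed, child seeds are derived via
`numpy.random.SeedSequence`, and rerunning a pipeline config reproduces
report artifacts bit for bit.

## Known limitations

* Sub-2 h gap handling before feature extraction is an assumption
  (profile-mean imputation); the original procedure is not documented.
* The short/long DFA crossover (90/120 min) is a convention, not a derived
  quantity.
* The stepwise entry thresholds are conventional defaults; the exact
  original stepwise cell grid is not reconstructible.
* External-validation quantities on synthetic cohorts depend on the
  realised test-score spread at a given seed; narrow-spread test sets make
  the random null easier and all baselines closer together — visible in
  the acceptance report as seed-to-seed variation.
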