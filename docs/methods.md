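# Methods

This note documents the models implemented in `mbfus`, the parameters that
matter, the design choices made where the design was genuinely open, and the
limits of what the synthetic experiments can show.

## Spectral band levels

A received pulse is reduced to dB-scale band levels relative to a baseline
spectrum (the mean of pre-microbubble pulses for the same target):

    level = 10 · log10( mean band power / mean baseline band power )

with the band the closed interval center ± halfwidth and the statistic the
*mean* power over bins, not the peak — robust to grid alignment. Defaults:
f₀ = 0.5 MHz, harmonics n·f₀ for n = 2…8, ultra-harmonics (k+½)·f₀ for
k = 1…7, broadband bin at 7.22·f₀ = 3.61 MHz, halfwidth 0.3 kHz. With 11 ms
records the spectral resolution is ≈ 91 Hz, so ±0.3 kHz spans ≈ 7 bins; the
narrow-halfwidth reading of the band width is recorded in `BandScheme`
rather than asserted as the only possible convention, and tests that build
coarse synthetic grids widen it explicitly. A broadband **event** is a level
strictly above 6 dB (3× the nominal 2 dB baseline noise SD); a tie at
exactly 6.0 dB is a non-event.

## Virtual subject

The simulator is a statistical plant, not a bubble-dynamics model (no
Rayleigh–Plesset, no skull aberration, no acoustic field). It produces the
structure the classifier and controllers assume:

- **Bolus kinetics** `C(t)`: 0 until injection (5 s), linear rise to 1 over
  `rise_time` (5 s), then `exp(−(t−t_peak)/τ)` with τ = 80 s (mouse preset)
  or 55 s (rat). Continuous, peak-normalized.
- **Threshold curve**: the 7th-harmonic mean is
  `C · L_max / (1 + exp(−s·(log10 P − log10 P50)))` with plateau
  L_max = 35 dB, midpoint P50 = 0.15 MPa, steepness s = 8 per decade —
  a saturating "linear then plateau" response. Other bands are fixed
  fractions of L7, peaking near the detector's 3.5 MHz sensitivity maximum.
  Gaussian noise (SD 2 dB) is added per band.
- **Collapse hazard**: per-pulse latch probability with odds
  `exp(k·(P·C^q − P_ic))`, k = 16, q = 1, P_ic = 0.37 MPa, multiplied by 3
  when C > 0.7 (transient high-concentration boost) and by 2 in
  tumor-bearing subjects. Hazard is exactly 0 at zero pressure or zero
  concentration. P_ic and k were calibrated once, at design time, so that
  the constant-pressure training protocol (pressures uniform on
  0.18–0.33 MPa, 130 pulses/target at 1 Hz) yields ≈ 8 % positive-class
  prevalence — the prevalence is a stated property of the training corpus
  this generator emulates; the hazard parameters themselves are free
  choices and must not be read as measured values.
- **Precursor latch**: a collapse latched at pulse *t* boosts that pulse's
  1st ultra-harmonic by `uh1_boost` = 6 dB (3× the band noise SD) and fires
  as a broadband event at *t+1* — *unless* the applied pressure at *t+1*
  fell below 97 % of the latching pressure, in which case the collapse is
  averted. Nothing in the underlying physics literature specifies how a
  pre-emptive pressure drop prevents an imminent collapse at this level of
  abstraction; this aversion rule is the minimal mechanic that makes the 5 %
  safety drop (×0.95 < 0.97) effective when applied *before* the event and
  ineffective when applied after, which is precisely the reactive/predictive
  distinction the controllers are built to expose.
- **Dose proxy**: cumulative `C · max(L7, 0)` per pulse, a monotone
  stand-in for opening strength. It is plumbing for benefit–risk analysis,
  not a calibrated permeability model.

All randomness flows through one seeded generator per subject; identical
seeds give bit-identical corpora and sessions.

## Precursor MLP

Features (12, fixed order): uh1…uh7, pressure, target x/y, microbubble
kinetics `C`, tumor flag. Label: broadband event at the *next* pulse (the
last pulse of each target is dropped). Split: stratified 80/20 over the full
corpus; the training portion is balanced by keeping every positive and an
equal count of seeded-random negatives; the test portion keeps its natural
≈ 8 % imbalance. (The balanced-train / natural-test structure is what makes
the characteristic metric profile — high accuracy and sensitivity, ~50 %
precision — reproducible.)

Architecture: 12 → 10 sigmoid → 1 sigmoid. Training minimizes the MSE of
the sigmoid output by Levenberg–Marquardt (`scipy.optimize.least_squares`,
`method="lm"`, analytic Jacobian, residuals = output − label), with min–max
feature scaling fitted on the training set only and a few seeded restarts
keeping the best final MSE. LM requires rows ≥ parameters (151 here); the
trainer rejects smaller sets. Labels use a strictly-greater 0.5 threshold.
The optimizer is recorded in the model metadata.

## Cross-attention classifier (AMP)

Subject-state features (x, y, pulse number, kinetics, pressure, tumor) are
encoded to a query; the 14 spectral measurements enter as a 14-token
sequence whose per-token affine+tanh encodings give keys and values;
scaled dot-product attention (`softmax(QKᵀ/√d)·V`), layer normalization,
dropout and a sigmoid head complete the model. Imbalance is handled in the
loss: the positive class carries weight `(n_neg/n_pos)·ε`, ε = 2. Model
selection is stratified 10-fold cross-validation (best validation balanced
accuracy wins). Latent dim 16, dropout 0.1, L2 1e-4, 300 epochs of
full-batch Adam at 0.01 are package defaults for sizes no external source
specifies. The whole network, including the attention backward pass, is
plain numpy with hand-derived gradients (verified against central
differences to ~1e-7); it exposes the same `predict` contract as the MLP so
controllers accept either.

## Controllers and the tracking state machine

Phase machine: `waiting → tracking → controlling → hold`, never backwards.
A 60 kPa tracking pulse interleaves each second and feeds only the tracker:

1. **Activation**: 4th-harmonic level ≥ baseline + 10 dB → `tracking`;
   the first controlled pulse follows one tracker update later.
2. **Decay monitoring**: the normalized H4 series (re its running peak) is
   fitted by least squares each pulse; after the minimum window (20 s
   mouse / 40 s rat) a fitted level ≤ 0.80 ceases control (`hold`).
3. **Hold**: the target-tracking update stops and pressure is maintained —
   but the *safety layer* stays armed to the 130 s end: events (all modes)
   and positive predictions (ML-CL) still trigger the 5 % drop. This
   reading is deliberate: the safety layer is defined independently of the
   control law, open-loop sessions show event-triggered reductions
   throughout, and whole-session event counts are the comparison currency.

Control laws, per therapeutic pulse:

- **OL**: pressure unchanged; on event, ×0.95 (and it stays there).
- **CL**: `P ← P · 10^(g·e/20)` with `e = L7_target − mean(last 3 L7)`,
  g = 0.5, step clipped to ±10 %, bounds [0.01, 0.5] MPa (0.4 MPa in the
  high-target benchmark); on event, ×0.95 instead.
- **ML-CL**: CL law, but the predictor is queried on the current pulse's
  features *first*; a positive prediction applies the safety drop and skips
  the upward update ("treat predicted events as if they had occurred").
  The exact CL update of the prior art is not public; the log-domain
  proportional law above is this package's choice satisfying the three
  stated roles (local fluctuation damping, target attainment, global decay
  mitigation). The ramp starts from the 60 kPa tracker pressure.

On a noise-free, event-free, non-decaying subject the CL law converges to
any target inside the curve's range; the suite asserts terminal L7 within
±1 dB of a 32 dB target (measured: |error| < 1e-7 dB). The demanding
benchmark target is 36 dB — *above* the L_max = 35 dB plateau — so the CL
arm ramps to its pressure ceiling and accumulates events, while the ML-CL
arm predicts precursors and averts them; open-loop arms run at the ML-CL
session's maximum and average pressures.

## Attribution

Interventional Shapley values: coalition value = mean model output with
coalition features from the sample and the rest from a background set
(default: a seeded 100-row subsample of training data). Exact enumeration
(2^d coalitions) is used for d ≤ 15 and as the oracle; the production
estimator is permutation sampling, deterministic under seed. Efficiency
(Σφ + baseline = f(x)) holds to machine precision for enumeration and to
< 0.01 for the sampler at the documented permutation counts. Global
importance is mean |φ| per feature, stable-sorted; partial dependence
reports a Spearman rank correlation, flagged undefined (and reported as 0)
for constant columns.

## Analysis

Session summaries use the 20 s window after microbubble arrival (first
non-waiting pulse): mean and sample SD (n−1) of L7, adjusted Fisher–Pearson
skewness (0 + flag for zero-variance windows). Event rates are
events/pulses with the strict >6 dB rule, additive over sessions. Relative
event reduction is `(1 − r_b/r_a)·100`. The treatment window's lower bound
is the smallest pressure whose opening proxy exceeds background mean + 2 SD;
the upper bound is the breakpoint of an exhaustive two-segment
piecewise-linear least-squares fit of broadband level vs pressure, flagged
open-ended when a single line fits essentially as well (SSE improvement
< 1 % of total spread). Variance comparisons provide both the classical
F-test (two-sided, ratio of sample variances) and Levene's test.

## Problem sizes and numerical choices

The default experiment sizes are the package's own: training corpora of 20
subjects × 4 targets × 129 labeled pulses (≈ 10,300 rows; the full-scale
105-subject corpus of ≈ 54,000 rows is exercised in an I/O test), benchmark
cohorts of 40 paired sessions, LM budgets of 400–1000 residual evaluations
with 2–3 restarts. Ties at decision thresholds are resolved
strictly-greater everywhere (event rule, classifier labels). Degenerate
inputs (single-class training sets, zero-variance groups, empty
backgrounds, bands outside the grid) raise `ValueError` rather than
returning silent defaults.

## Known limitations

- The virtual subject is statistical: no bubble physics, no spatial field,
  no skull, no vascular heterogeneity. Passing tests show the *pipeline*
  behaves as specified under the assumed structure, not that the classifier
  or controllers would reach the same numbers on animal data.
- The precursor is a single-band, one-step signature by construction;
  real pre-collapse signatures are richer and possibly longer-range.
- The dose proxy is monotone plumbing, not a permeability model; treatment
  window lower bounds derived from it are illustrative.
- The hazard's >70 % concentration boost and tumor odds multiplier are
  qualitative structure with free magnitudes.
- LM training is full-batch and in-memory; it is sized for 10³–10⁴-row
  balanced sets, not for large-scale corpora.
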