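# Methods

## Problem and model

The package estimates the continuous gait phase — the position within one
gait cycle, expressed as 0–100 % from one right heel strike to the next —
at every 10 ms sample of a bilateral insole recording, while the wearer
moves over mixed terrain. The input is ten logical force-sensing-resistor
(FSR) channels: five anatomical sites (toe, first metatarsal, fifth
metatarsal, cuboid, heel) per foot, sampled at 100 Hz. Where an insole
carries paired physical sensors per site, they are assumed pre-summed into
one logical channel per site.

Estimation is a serial cascade of two bidirectional LSTM models:

1. **Walking-condition (WC) classifier.** A 100-sample causal window of the
   ten normalized channels is classified into one of five conditions —
   level walk (LW), stair ascent (SA), stair descent (SD), ramp ascent
   (RA), ramp descent (RD). Stack: Bi-LSTM(128) → dropout 0.25 →
   Bi-LSTM(64) → dropout 0.25 → dense 64 → 5-way softmax; categorical
   cross-entropy loss.
2. **Phase estimator.** A 25-sample window of the chosen feature variant is
   regressed onto the continuous sinusoidal encoding of phase,
   (cos θ, sin θ) with θ = phase·2π/100, which removes the 0/100 wrap
   discontinuity. Stack: Bi-LSTM(128) → dropout 0.25 → Bi-LSTM(32) →
   dropout 0.25 → dense 2 → linear 2; mean-squared-error loss. The decoded
   phase is the four-quadrant arctangent of the output pair, mapped to
   [0, 2π) and rescaled to [0, 100); decoding is therefore invariant to
   radial scaling of the pair, and predicted pairs need not be unit norm.

Both models train with Adam (learning rate 0.001), batch size 100, and
early stopping with patience 5 on validation loss (best weights restored).
The classifier optionally uses k-fold cross-validation (default 5 folds)
over the pooled training windows, returning the best fold's model.

Feature variants for the estimator (widths in parentheses): #1 = 10 FSR +
4 regional sums + 5-dim one-hot WC code (19); #2 drops the WC code (14);
#3 drops the regional sums (15); #4 keeps only sums + WC (9); #5 adds the
two per-foot centre-of-pressure values to #1 (21). Regional sums are
Fore = toe + 1st-meta + 5th-meta and Back = cuboid + heel per foot, each
divided by its training-set maximum. During estimator *training* the WC
one-hot uses ground-truth labels (teacher forcing), which decouples the
stages; at *inference* the classifier's argmax is always injected, held
constant between classifier exports.

The recurrent core is implemented directly in NumPy (`_recurrent.py`) with
explicit backpropagation through time; gradients are verified against
finite differences in the test suite. Gate order is (input, forget, cell,
output), forget biases start at 1, kernels are Glorot-uniform and
recurrent kernels orthogonal per gate block. Everything is float64 and
deterministic given the seeds.

## Signal processing

* **Normalization.** Per-channel min–max scaling with statistics fit on
  training recordings only and frozen; held-out values are clipped to
  [0, 1]. No filtering or smoothing is applied anywhere. Statistics are
  fit per subject on that subject's training recordings — each subject's
  data is normalized by their own range, as an insole pipeline would do in
  practice.
* **Heel-strike detection.** An upward crossing of threshold 0.05
  (normalized units) on the right-heel channel, with a 300 ms refractory
  period, then refined by walking back along the monotone loading ramp to
  the last sample at or below a 0.02 baseline (≤ 30 samples). The
  refinement reports initial contact rather than the threshold instant,
  whose lag would otherwise vary with heel-loading amplitude across
  conditions. All constants are configurable.
* **Phase labelling.** Phase 0 at each detected strike, linear to 100
  (exclusive) at the next; samples before the first and after the last
  strike are flagged invalid, never extrapolated.
* **Windowing.** Trailing (causal) windows labelled at their final sample;
  windows spanning a condition transition take the final sample's label.
* **Stride normalization.** Each stride linearly interpolated onto a
  101-point 0–100 % grid and grouped by condition, for mean ± SD loading
  curves.

## Error metrics

Per-sample phase error is circular: e = ((est − true + 50) mod 100) − 50.
This choice follows from the sinusoidal encoding, which makes phase
periodic; a non-circular mode exists behind a flag. RMSE and APEE (mean
|e|, in % of the cycle) are computed from e. R² is computed on the CSF
pair — the actual regression targets — pooled over both components
(1 − SSres/SStot); a phase-domain R² would hide radial miscalibration of
the outputs. rRMSE divides RMSE by the mean estimated phase (undefined and
flagged when that mean is 0); NRMSE divides RMSE by the 100-unit phase
range, so numerically NRMSE in percent equals the RMSE. APEE here is
defined as the mean absolute circular phase error; published uses of the
name do not always print a formula, so this is the package's fixed
definition. Headline aggregates are unweighted means of per-condition
values; own-subject numbers average the diagonal of the (training subject
× testing subject) grid, cross-subject numbers the off-diagonal.

## Synthetic data generator

No public dataset exists for this sensor layout and protocol, so the
simulator is a first-class module. Each walking condition has a stride
template: per-site loading curves on the 0–100 % cycle built from smooth
attack/decay bumps (sin² rise, cos² fall; a symmetric bump is a raised
cosine). Heel contact leads the cycle with a short 5-unit attack so the
rising edge is sharp, as a real heel impact is; midfoot and forefoot
follow. Condition signatures: LW heel-to-toe progression; SA
forefoot-dominant with a light heel; SD sharp heel/forefoot impacts with a
quiet midfoot; RA forefoot-shifted timing with longer stance; RD
heel-dominant with reduced toe loading. The left foot runs the same
template half a cycle out of phase. All supports end by ~90 % of the
cycle, so each foot unloads during its swing.

Subjects drawn by `make_cohort` differ in: per-channel amplitude
(lognormal, σ = 0.25), cadence (normal, 52 ± 3 strides/min, clipped to
45–58), per-condition stance fraction (base 0.62/0.64/0.58/0.66/0.63 for
LW/SA/SD/RA/RD, subject jitter σ = 0.03, clipped to 0.45–0.75, which
stretches template timing), per-channel onset shifts (uniform ±3 phase
units; heel pinned at 0 so the phase anchor stays defined), stride-timing
jitter (σ = 15 ms per stride) and additive Gaussian sensor noise
(σ = 0.02 normalized units, truncated at 0). These values were chosen once
as plausible for healthy adults walking at comfortable speed; the
amplitude/timing spread is what makes cross-subject testing genuinely
harder than own-subject testing. Condition transitions happen at right
stride boundaries, so ground-truth phase stays well defined across
segments.

What the simulator does **not** emulate: biomechanically calibrated force
magnitudes (newtons, body weight), double-support micro-dynamics,
speed–amplitude coupling, fatigue or drift, sensor hysteresis and
saturation, surface compliance (paved/unpaved variants), or pathological
gait. Passing the end-to-end checks therefore shows the pipeline is
correct and learnable on stride-periodic data with realistic inter-subject
variation — not that the printed accuracies transfer to any particular
hardware or cohort.

## Study protocol on synthetic data

The protocol mirrors the study design: three scenarios (level course;
stair course LW–SA–LW–SD–LW; ramp course LW–RA–LW–RD–LW), each performed
three times per subject; the third trial of every scenario is held out for
testing and the rest is split 80/20 into contiguous train/validation time
blocks (contiguous, so overlapping windows cannot leak across the split).
One classifier is trained on all subjects; one phase estimator per subject
(the per-subject grid requires it), teacher-forced on ground-truth
condition codes.

Default sizes of a full run (`experiments.StudyConfig`): 4 subjects,
3 scenarios × 3 trials, 30 level strides or 8–10 strides per segment
(≈ 40 s of gait per trial, ≈ 150 k samples total), classifier windows
every 75 samples for ≤ 10 epochs without cross-validation, estimator
windows every 10 samples for ≤ 12 epochs, evaluation every 15 samples.
These sizes keep a complete study — simulation, two training stages for
five models, and a 4 × 4 evaluation grid — around ten minutes on one CPU
core while leaving each training set in the thousands of windows; they are
deliberate scale-downs of the ten-subject protocol, not tuned quantities.

## Numerical and design choices

* Eq.-style piecewise decoding of (cos θ, sin θ) that branches only on the
  sign of the sine is ambiguous for negative cosine; the four-quadrant
  arctangent agrees with it wherever it is defined and is used throughout.
* The estimator input is the full 14 FSR-derived features plus the WC code
  (width 19) for variant #1, and the estimator sequence length is 25.
* The classifier's dense head uses ReLU and the estimator's 2-unit dense
  head uses tanh (bounded like its targets); output layers are linear
  (softmax applied in the loss for the classifier).
* Dropout is inverted dropout: identity at inference.
* A dead-zero CSF output at inference would have no defined angle; the
  pipeline maps it to phase 0 instead of failing (decode_phase itself
  raises on an explicit zero vector).
* Max–min degenerate channels (max = min) raise, naming the channel.
* Centre of pressure holds its last valid value through swing (0 at the
  start), rather than emitting NaNs into the feature matrix.
* Maximum training epochs default to 100 with early stopping; scaled study
  runs cap epochs explicitly.

## Known limitations

* Synthetic-only validation: absolute RMSE/R² values depend on the
  generator's noise and inter-subject spread and are not comparable 1:1 to
  hardware studies.
* The NumPy LSTM trains on one core; wall-clock cost grows linearly with
  window count and sequence length, so large cohorts call for window
  subsampling (the `hop` parameters).
* The classifier's per-sample output is piecewise constant between window
  exports; at condition transitions up to one window of lag is inherent to
  the causal design.
* rRMSE depends on the mean *estimated* phase and is unstable for short
  segments; it is reported for comparability, not recommended as a
  primary metric.
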