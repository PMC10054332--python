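# Methods

This note documents the models, numerical choices and limitations of the
`graphoscreen` pipeline. It is written for someone who wants to understand
or modify the method, not just run it.

## Data model and preprocessing

A session is one execution of one game by one child at one time-point:
samples of (timestamp, x, y, pressure, altitude, azimuth) at a declared rate
(240 Hz by default). Cleaning is deterministic and ordered:

1. **Resample** to 50 Hz by linear interpolation onto the uniform grid
   `t₀ + k/50` for `k = 0..⌊span·50⌋`. The 240→50 Hz factor is non-integer
   (4.8), so interpolation, not decimation, is used; no anti-alias filter is
   applied (the signals of interest are far below 25 Hz).
2. **Truncate** ⌊0.05·L⌋ samples from each end (border effects).
3. **Normalize**: time affinely mapped to [0, 1]; x and y shifted so the
   first sample is the origin; altitude/azimuth dropped (near-constant,
   uninformative). Pressure is not re-zeroed.
4. **Group by ID**: executions sharing a difficulty group (the A/W ratio for
   tunnels, the copy modality for copy games) are linearly resampled onto a
   common uniform grid of **G = 101** points on [0, 1] and averaged
   pointwise. Executions of unequal length are only comparable on this grid;
   G = 101 makes the window layout (length 50, hop 5) produce 11 windows per
   representative series.

Labels: three handwriting-test z-scores per child; the global score is their
median and the child is at risk iff it is strictly below −2. Children
without labels are dropped at load time.

## Synthetic cohort generator

The generator emulates the acquisition protocol — 3 copy-mode executions per
copy game, 15 tunnel executions in 5 (square) / 8 (word) distinct A/W
groups, presented in per-child random order — with a statistical structure
the pipeline can legitimately exploit:

* **Latent ability** `a ~ N(0,1)`, shifted by `−effect_size` for children
  drawn at risk with the target prevalence (default 0.18).
* **z-scores** `z_j = a + shift + 0.3·ε_j`. The shift is calibrated
  semi-analytically: the probability that the median of the three noisy
  scores falls below −2, integrated over the ability mixture with
  Gauss–Hermite quadrature (101 nodes), is solved for the target prevalence
  by Brent root finding (achieved prevalence accurate to ~1e-3). The label
  is then derived from the simulated z-scores by the same median rule used
  for real data, so label noise relative to the intended class is present,
  as in the study population.
* **Signals**: each channel is a sum of 2–4 sinusoids with frequencies
  uniform in 1–5 cycles per execution plus Gaussian noise (`noise_sd`,
  default 0.05 of the channel scale). Labelled at-risk children receive one
  extra "tremor" component at 8–12 cycles per execution with amplitude
  `0.3·effect_size` of the channel scale. Frequencies are defined on the
  normalised time axis so the class structure survives time rescaling. The
  frequency-coded effect matches the domain finding that frequency-related
  features discriminate handwriting difficulties best.
* Durations are uniform in 1.5–3.0 s at 240 Hz; the tunnel A/W values are
  package defaults (the real app's geometries are unpublished).

What the generator does **not** model: biomechanical kinematics (isochrony,
homothety, speed–accuracy trade-off), stroke lifts, cohort dropout, age
drift across time-points (it defaults to a single time-point, y1), or
device-specific pressure nonlinearity. Passing tests on this cohort
demonstrate that the pipeline recovers a frequency-coded class difference
end to end; they do not certify performance on real children.

`generate_labels` exposes the label model alone, so prevalence calibration
can be measured at n = 10,000 without materialising ~10⁹ signal samples.

## Sinusoidal embedding (Time2Vec autoencoder)

Each representative channel is cut into windows of 50 samples every 5. One
autoencoder per (child, time-point, game, ID, feature) is trained on that
signal's windows only:

* **Encoder**: affine map producing one encoded scalar per window
  coordinate, `E = XW + c`.
* **Latent layer**: the Time2Vec map applied to each encoded scalar with
  shared learnable parameters — `h₀ = ω₀E + φ₀`, `hᵢ = sin(ωᵢE + φᵢ)` for
  `i = 1..s` (s = 9 by default).
* **Decoder**: one shared weight vector `p` (plus per-coordinate bias)
  recombining the s+1 channels to reconstruct each coordinate.

The extracted representation is (ω₁..₉, φ₁..₉, p₁..₉); the linear term is
excluded from features and used only for reconstruction. Pulsations are
canonicalised to ω ≥ 0 (sign flips absorbed into φ and p).

**Training.** Full-batch Adam (lr 1e-3) on the mean squared reconstruction
error, up to 2000 epochs with plateau stopping (no 1e-8 improvement for 100
epochs) and best-loss snapshotting. All fits for one (time-point, game) are
trained batched in float32 — thousands of ~3k-parameter models become a few
batched matmuls per epoch.

**Initialisation matters.** The loss is highly oscillatory in ω, and the
architecture admits an identity shortcut (a small-ω component acting as a
linear pass-through of the window values) that reconstructs well while
leaving the pulsations meaningless. Two data-driven initialisations avoid
both failure modes:

* ω, φ, p start at the strongest local peaks of the zero-padded (8×) Welch
  periodogram of the windows (phases from the first window's spectrum);
  slots beyond the available peaks fall back to uniform draws over
  [0, 2π·8] rad.
* The encoder bias starts as the window-local time grid and the encoder
  weights as the min-norm ridge regression from window values to window
  start time, so the encoded scalar approximates absolute time from epoch 0
  and the learned ω stay in radians per unit of normalised time.

Adam then refines all parameters jointly. On clean fixtures this recovers a
pure sinusoid's frequency within 0.31 rad and reconstructs a two-sinusoid
signal to MSE ≈ 6e-7.

**A structural caveat.** Because (ω, φ, p) are shared across windows while
windows of a periodic signal differ by phase, exact reconstruction requires
the encoder to recover each window's start time from its values. For signals
whose window matrix is low-rank (a noiseless sinusoid cut into many
windows), that map does not exist in the encoder's linear family and a
reconstruction floor remains; for realistic (noisy, multi-component) signals
the window matrix is full-rank and the floor vanishes. Reconstruction
fixtures in the tests therefore use short signals (3 windows) where exact
phase compensation exists.

## Curves, landmarks, Procrustes distance

The s sinusoids are recombined on a 501-point grid over [0, 1] (fine enough
that band-limited combinations with ω ≤ 2π·8 are resolved to < 1e-2):

* `abs_weighted_mean`: weights |pᵢ|/Σ|pⱼ| — a convex combination of sines,
  hence bounded in [−1, 1];
* `weighted_sum`: raw signed weights pᵢ — unbounded.

Landmarks are the strict local extrema (discrete sign changes of the
difference; plateaus contribute their midpoint once; endpoints excluded),
taken as (t, v) points. The N extrema with largest |v| are kept (ties by
earlier time). Matching between two sets of equal N is positional after
sorting both by |v| descending (value order) or by t ascending (time
order).

The distance is the full Procrustes disparity: both point sets are centred,
scaled to unit Frobenius norm, and aligned by the optimal orthogonal map
(reflection permitted) with the optimal isotropic scale; the residual is
`1 − (Σσ)²` where σ are the singular values of the cross-covariance. This
matches `scipy.spatial.procrustes` (used as an independent cross-check in
the tests; the implementation is our own batched SVD, which evaluates one
cohort against a reference landmark set in a single vectorised call).
N = 2 is allowed; collinear sets are handled by the closed form.

## Risk classifier and nested cross-validation

For a configuration (mode, scheme, N): per (ID, feature) unit, the training
children's curves are averaged, N landmarks selected on the average, every
child's disparity computed, and the F1-optimal distance threshold chosen
among the midpoints of consecutive distinct values plus one candidate below
the minimum and one above the maximum (ties → smallest threshold; a unit
votes at-risk when the distance **exceeds** its threshold — outliers
relative to the cohort average). The positive-vote fraction is the risk
probability; the probability threshold is F1-optimised the same way with an
inclusive ≥ rule and candidates extended by 0 and 1. F1 with zero predicted
positives is 0. Units whose average curve has fewer than N extrema are
dropped (and stay dropped at prediction); children lacking N extrema in a
unit are skipped by that unit and their probability renormalises over the
remaining units.

**Nested CV** (k = 5): stratified outer partition; per outer fold, 5 inner
validation subsets drawn as independent stratified 25% subsamples of the
outer-train (they may overlap — this keeps validation sets a usable size in
small cohorts). Per configuration and inner fold, N is tuned on the inner
validation set over `n_range` clipped to the landmarks available on every
unit's average curve; the configuration with the best mean inner-validation
F1 wins the outer fold. Test children receive the mean of the 5 inner
classifiers' probabilities, thresholded at the mean of their probability
thresholds. All outer-test predictions are concatenated and scored once
(micro-averaging). Test labels are never touched during fitting or
selection — permuting them leaves the fitted classifiers bit-identical
(tested).

## Blending meta-model (Quasi-SVM)

The meta-training set has one row per child with four features: the mean of
the child's inner-validation probabilities per game (children missing a game
are imputed with the column mean). The meta-test set uses the single
outer-test probability per game. The model maps features through a frozen
random Fourier expansion `z = √(2/D)·cos(XW/γ + b)` (D = 512, `W ~ N(0,1)`,
`b ~ U(0,2π)`, trainable log length-scale γ), then a single affine output.
The sigmoid output is affinely mapped to (−1, 1) and trained with
class-weighted hinge loss (weights n/(2·n_class)) against labels in
{−1, +1}: Adam at 1e-4, at most 1000 epochs, stratified 80/20
train/holdout split, early stopping with patience 50, best-epoch weights
restored. Predicted probability is the sigmoid; the decision is strict
(output > 0), so a zero decision scores negative.

## Determinism and problem sizes

Every stage seeds its randomness from the run's global seed by hashing the
stage name (CRC-32) into a `SeedSequence`; identical configurations produce
byte-identical summaries. The test suite and the acceptance script run the
end-to-end experiments at 60 children, one time-point, autoencoder budget of
150 epochs and `n_range` 2–6 — sizes chosen so a full run takes about a
minute on one CPU while leaving the class signal clearly recoverable; the
library defaults (2000 epochs, `n_range` 2–10) are what one would use for a
real analysis.

## Known limitations

* Cohort performance numbers on the real longitudinal study are not
  reproducible here (data unavailable); tests validate metric identities,
  protocol constants, invariants, and recovery on synthetic cohorts.
* The autoencoder is univariate per channel; no cross-channel latent.
* Landmark matching is positional after sorting; no optimal-assignment
  search, and no curvature-based landmark alternatives.
* The vote direction (large distance → at-risk) is fixed, not searched.
* The Quasi-SVM expansion width and learning schedule are fixed defaults;
  no hyperparameter search is performed.
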