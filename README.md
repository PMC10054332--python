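# graphoscreen

Early screening of **dysgraphia risk** from tablet stylus recordings, before
handwriting is mastered. Children in their last year of kindergarten play
drawing "serious games" on a tablet (copying symbols, tracing through tunnels
of varying difficulty) while the stylus streams position, pressure and
inclination at 240 Hz. Years later, a standardized handwriting battery yields
three exercise z-scores per child; a median z-score below −2 marks the child
as at risk. `graphoscreen` implements the full analysis pipeline that links
the early drawing signals to that later label:

1. **Cleaning** — each execution is resampled to 50 Hz, trimmed by 5% at each
   end, position-zeroed at the first sample, and put on a common [0, 1] time
   axis; the 15 tunnel executions are averaged into one representative series
   per Index of Difficulty (ID = amplitude/width; 5 distinct IDs for the
   square tunnels, 8 for the word tunnels).
2. **Sinusoidal embedding** — one tiny autoencoder per signal whose latent
   layer is the Time2Vec map

   `t2v(τ)[i] = ω₀τ + φ₀ (i = 0); sin(ωᵢτ + φᵢ) (1 ≤ i ≤ s)`

   with s = 9 learnable sine components. The learned pulsations ω₁..₉, phases
   φ₁..₉ and decoder weights p₁..₉ compress a signal of hundreds of samples
   into three length-9 vectors (the linear i = 0 term is kept only for
   reconstruction).
3. **Shape distance** — the s sinusoids are recombined into a periodic curve
   (|p|-weighted mean, bounded in [−1, 1], or signed-p weighted sum), its N
   strongest extrema become landmarks, and each child's landmark set is
   compared to the cohort-average curve by full **Procrustes analysis**
   (translation, isotropic scale and rotation/reflection removed; the
   residual disparity is the distance).
4. **Risk classification** — per (ID, feature) a distance threshold is chosen
   to maximise F1; the units vote, the positive-vote fraction is the child's
   risk probability, and an F1-optimal probability threshold classifies.
   Aggregation mode, matching scheme and N are tuned inside a **stratified
   nested 5-fold cross-validation** with overlapping inner validation folds.
5. **Blending** — the four per-game classifiers' out-of-fold probabilities
   feed a **Quasi-SVM** meta-model: a frozen random-Fourier-feature expansion
   with trainable kernel scale and a single output unit trained with
   class-weighted hinge loss.

The study data are not publicly distributable, so the package ships a
synthetic cohort generator (`graphoscreen.simulate`) that reproduces the
acquisition protocol and plants a frequency-coded class effect: at-risk
children receive an extra 8–12 cycles-per-execution "tremor" component, and
their z-scores are tied to a latent ability calibrated so that the expected
at-risk fraction matches a target prevalence (default 18%).

## Worked example: recovering frequencies from one signal

```python
import numpy as np
from graphoscreen import SineAutoencoder, TrainSpec

t = np.arange(60) / 50.0
signal = np.sin(2*np.pi*2*t) + 0.5*np.sin(2*np.pi*5*t)
res = SineAutoencoder(signal, TrainSpec(seed=0, dt=1/50)).fit()
print(res.summary())
```

```
                 Sinusoidal decomposition
==========================================================
components (s):    9    windows:    3    recon MSE: 6.435e-07
----------------------------------------------------------
  i  omega (rad/u)  freq (cyc/u)  phi (rad)          p
  1        12.6102        2.0070     0.0635     0.9590
  2        31.4350        5.0030     0.0114     0.5753
  ...
```

The two dominant components (largest |p|) sit at 2.007 and 5.003 cycles per
unit time — the true 2 Hz and 5 Hz content — with amplitudes ≈ 1 and 0.5,
and the windows are reconstructed to a mean squared error of 6.4e-7.

## Worked example: the full screening pipeline

```python
from graphoscreen import RunConfig, run_pipeline, CohortConfig, TrainSpec

cfg = RunConfig(
    simulation=CohortConfig(n_children=60, effect_size=3.0, seed=11),
    seed=11, train=TrainSpec(epochs=150), n_range=tuple(range(2, 7)))
report = run_pipeline(cfg)
```

With 60 children (13 at risk) this prints, per game and for the meta-model,
the micro-averaged metrics over the concatenated outer test folds:

```
copy_sequence  acc  75.0%  F1  28.6%
copy_square    acc  61.7%  F1  25.8%
tunnel_square  acc  81.7%  F1  42.1%
tunnel_word    acc  70.0%  F1  30.8%
quasi_svm      acc  73.3%  F1  46.7%  precision  41.2%
baseline       acc  78.3%  F1   0.0%
```

Every game classifier and the blended Quasi-SVM beat the all-negative
baseline's F1 of 0; the meta-model blends the four noisy per-game signals
into the best F1. `report.summary_json()` carries the same numbers
machine-readably, and `RunConfig(out_dir=...)` writes prediction CSVs and
metric JSONs.

A CLI mirrors the stages: `graphoscreen simulate | embed | fit | evaluate |
blend | run` (see `graphoscreen --help`).

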