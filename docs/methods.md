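# Methods

## The model

A labelled beat is a pair (x, y) with x ∈ R^W a single-cycle window
(default W = 300 samples at 360 Hz, R wave at the window midpoint) and
y ∈ {N, A, V, L, R}. After denoising and per-beat min-max normalisation,
beats are projected into the top-k eigenvector basis of the training-fold
covariance, z = C (x − μ), k = 16 by default. Everything downstream —
pretraining, adversarial training, synthesis, gating, and the final
classifiers — operates on these component vectors; waveforms are
recovered only for inspection via the affine pseudo-inverse x̂ = Cᵀz + μ.

Two training stages follow. Stage 1 fits a conditional encoder/decoder by
mean-squared reconstruction of z given the class label. Stage 2 trains a
conditional generator and critic with the WGAN-GP objective (penalty
weight λ = 10, interpolates ẑ = εz_real + (1−ε)z_fake with ε ~ U(0,1) per
sample), two critic updates per generator update, and auxiliary L1/L2
terms that pull the per-class mean of decoded fakes toward the per-class
mean of the real minibatch. The generator emits codes in the encoder's
latent space; fakes are decoded before scoring, so the critic always
compares in PCA space (a flag switches to latent-space scoring, which
interprets the alternative reading of the two-stage design; with
latent_dim = k the two coincide in shape). A vanilla log-loss GAN mode is
retained for comparison.

Synthetic batches enter the training pool through a strict-improvement
gate: a surrogate random forest is retrained on pool ∪ candidates and
scored on a dedicated validation split (never the test fold); the batch
is kept only if the gate metric (macro F1 by default) strictly exceeds
the running baseline, which then ratchets up. Ties reject. The majority
class is never augmented.

## Conditioning and backbones

Both backbones receive the class label as a learned embedding
(256-dimensional at full scale). The transformer backbone tokenises each
scalar component (shared scalar→width projection plus a learned
positional embedding), prepends the projected class embedding as a
conditioning token, applies two pre-LayerNorm blocks with 8 heads at
width 512, and reads out from the conditioning token. The MLP backbone
concatenates the component vector with the class embedding and applies
two leaky-ReLU layers. Full-scale capacities (2 layers, 8 heads, width
512, embedding 256, Adam 1e-4 with β = (0.5, 0.999), batch 32, 500
epochs) are the package defaults; desk-scale runs shrink width and epochs
(below).

Minibatches in both stages are drawn with inverse-class-frequency weights
by default. Without this, rare classes receive almost no gradient share
at small scale and the conditional structure never forms for them (we
observed generated minority means collapsing toward the majority
centroid). Plain epoch-shuffled iteration is available via
`balanced_sampling=false`.

## The autodiff engine

The networks run on a compact numpy reverse-mode engine
(`cardioaug.nn.autograd`). Every op's vector-Jacobian product is itself
expressed in engine ops, so gradients can be differentiated again
(`create_graph=True`); the gradient penalty — a function of the critic's
input gradient — therefore backpropagates exactly, which the test suite
verifies against finite differences through attention layers. All
arithmetic is float64, giving bit-identical runs for a fixed seed and
thread count.

## The synthetic beat simulator

Each class is a sum of Gaussian bumps standing in for P/Q/R/S/T waves:
N has a normal P-QRS-T; A an earlier, taller P with normal QRS; V a wide
QRS, absent P and inverted T; L and R widened, notched QRS complexes with
opposite asymmetry. Defaults (all configurable):

| parameter | default | meaning |
|---|---|---|
| window_len / fs | 300 / 360 Hz | single-cycle window |
| class proportions | N .778, A .0211, V .0756, L .0713, R .0539 | benchmark imbalance |
| wave_center_jitter_sd | 0.008 (window fraction) | beat-to-beat wave timing |
| wave_amp_jitter_sd | 0.15 (lognormal σ) | beat-to-beat wave amplitude |
| amplitude_jitter_sd | 0.10 (lognormal σ) | whole-beat gain |
| patient_scale_sd / patient_offset_sd | 0.15 / 0.05 mV | patient effects |
| noise_sd | 0.05 mV | white noise |
| baseline_wander_amp / hz | 0.10 mV / 0.5 Hz | respiration-like drift |
| powerline_amp / hz | 0.02 mV / 60 Hz | mains interference |

The per-wave jitter levels were chosen so that the baseline classifier
shows a *scarcity-driven* minority deficit: with ~30 A training beats the
random forest recalls roughly 90% of A beats while all other classes sit
at ~95–100%, and augmenting A with samples from its true distribution
repairs the recall without costing macro precision. Larger jitter makes
the A/N overlap irreducible (even ideal augmentation then trades
precision for recall), which does not match the behaviour this method is
designed to exhibit on real data. Noiseless default templates remain
exactly nearest-centroid separable, and ≥500 denoised default beats put
≥90% of variance in the first 7 components.

What the simulator does **not** model: rhythm context (every beat is an
isolated cycle), QT/RR adaptation, electrode artefacts beyond stationary
sinusoids, multi-lead geometry, and real inter-patient morphology
families. Passing tests on it demonstrate that the pipeline's mechanics
(conditioning, gating, metric conventions) behave as designed — not that
clinical-grade augmentation quality is reached on real records.

## Denoising

Multi-level DWT with symmetric extension, db7 at 9 levels by default;
level-wise soft thresholding at σ̂√(2 ln n) with σ̂ = median(|d₁|)/0.6745
from the finest detail band. Nine db7 levels need far more than 300
samples, so denoising is intended for continuous records before beat
extraction; on isolated beats the depth auto-reduces with a warning. The
threshold rule and soft/hard mode are configurable; `none` gives perfect
reconstruction (tested to 1e−8).

## Numerical conventions

- PCA components carry a fixed sign (largest-|loading| entry positive) so
  fitted spaces and component heat maps are comparable across runs;
  explained-variance ratios are fractions of total variance.
- NPRD follows the classical percent convention (×100); with min-max
  normalised beats the amplitude range is 1, so NPRD equals classical PRD
  percent. Because PRD itself is scale-free, dividing by the range makes
  NPRD scale as 1/c under joint rescaling, while NRMSE and NMAE are
  exactly invariant.
- The NMAE is the standard mean absolute error over the range.
- Macro aggregates are unweighted means over the five classes; the "std"
  reported next to them is the sample standard deviation (n−1) of the
  five per-class values.
- Augmentation ratios are truncated, not rounded, at three decimals.
- A class with zero predicted positives gets precision 0 with an explicit
  flag in the report.
- Gate ties reject; the recorded baseline sequence is strictly
  increasing.
- k-fold splits are beat-stratified by default (a patient-grouped mode is
  available); classes smaller than the fold count degrade to an
  unstratified split with a warning.

## Desk-scale configuration

`small_synthetic_config()` is the configuration used by the test suite
and the acceptance script: ~2,000 synthetic beats (A at ~2%), k = 16,
MLP backbone at width 32, 60 stage-1 epochs at lr 1e-3 and 120 stage-2
epochs at lr 5e-4, gate surrogate of 60 trees, evaluation forest of 200
trees. The raised learning rates compensate for the shortened schedules;
full-scale defaults keep Adam 1e-4 / 500 epochs. The whole end-to-end
run finishes in well under a minute on one CPU core.

## Known limitations

- The record reader covers the format-212 / MIT-annotation subset used by
  the arrhythmia benchmark, not the full WFDB family (no multi-frequency
  signals, no format 16/80, no aux-string semantics).
- The acceptance gate retrains its surrogate per candidate batch; for
  very large pools a cheaper incremental surrogate would be preferable.
- Latent-space discrimination is implemented but lightly exercised; the
  PCA-space default is the tested path.
- The transformer backbone at full width (512) trains slowly on the
  numpy engine; it is intended for correctness and small-scale studies
  rather than long full-capacity runs.
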