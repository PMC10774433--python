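# Methods

This note documents the modeling and numerical choices behind
`fecgdenoise`: what each component assumes, which parameters matter and
why their defaults are what they are, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Denoiser architecture

The denoising filter is f = f_D ∘ f_E on standardized 4×1920 windows
(four abdominal leads, 1920 samples at 500 Hz ≈ 3.84 s).

**Encoder** — eight layers of (dilated 1-D convolution, kernel 8 →
LeakyReLU(0.2) → affine instance normalization). Channel counts
4→16→32→64→128→256→512→1024→2048; layers 1–7 halve the temporal extent
(stride 2), layer 8 keeps it (stride 1), giving a 2048×15 latent code.
Dilations are 2 on layers 1, 2, 7, 8 and 4 on layers 3–6, widening the
receptive field across the beat without extra parameters.

**Padding.** With kernel 8 the layer geometry fixes the padding
uniquely from the convolution length formula
`L_out = ⌊(L_in + 2p − d(k−1) − 1)/s⌋ + 1` and its transposed
counterpart `L_out = (L_in−1)s − 2p + d(k−1) + op + 1`:

| layer type            | p  | op |
|-----------------------|----|----|
| conv s=2, d=2         | 7  | —  |
| conv s=2, d=4         | 14 | —  |
| conv s=1, d=2         | 7  | —  |
| conv s=1, d=1 (final) | (3, 4) asymmetric | — |
| tconv s=1, d=2        | 7  | 0  |
| tconv s=2, d=2        | 7  | 1  |
| tconv s=2, d=4        | 14 | 1  |

A unit test derives every layer's output shape and parameter count from
these values rather than trusting the table above.

**Decoder** — mirror image with transposed convolutions, plus a final
plain convolution 4→4 (no activation, no normalization) so the output
is unbounded, as a regression target requires. Encoder activations of
layers 1, 3, 5, 7 (taken after instance normalization) are concatenated
channel-wise onto the inputs of decoder layers 8, 6, 4, 2. Concatenation
rather than addition is forced by the decoder parameter counts (those
layers see doubled input channels). The network is fully convolutional:
any window length that survives the seven halvings works, and doubling
the input length doubles every temporal extent.

**Discriminator** — an MLP on the flattened window,
7680→1920→480→120→1 with ReLU between layers and a sigmoid output. The
feature map used for feature matching is the penultimate 120-unit
post-ReLU activation (configurable in principle; the penultimate layer
is the conventional choice for feature matching).

**Instance normalization** carries a learnable scale and shift per
channel (2 parameters per channel, matching the per-layer counts) and
uses ε = 1e-5 in the variance denominator so all-zero inputs stay
finite.

**Initialization** is fan-in-scaled uniform, U(−1/√fan_in, +1/√fan_in),
for all weights and biases, with a seed-controlled generator.

**width_scale** multiplies every channel count (and the discriminator's
hidden widths) by a factor in (0, 1], rounded to at least 1. It exists
so the identical topology can be trained in minutes on one CPU;
width_scale = 1 is the full architecture and the default everywhere
except the desk-scale experiments noted below.

## Objective

With x the clean window, x̂ its noisy pair, ẑ = f_E(x̂), z = f_E(x),
x̃ = f_D(ẑ):

* L_rec = MSE(x, x̃), computed per channel and averaged;
* Ω = ‖∂f_E(x̂)/∂x̂‖²_F, the contractive penalty that makes the code
  insensitive to input perturbations (L_ctr = L_rec + Ω);
* L_adv = MSE between discriminator features of x and of x̃
  (feature matching — more stable than the saturating GAN loss);
* L_enc = MSE(z, ẑ), pulling the codes of clean and noisy versions of
  the same signal together;
* total L = w_enc·L_enc + w_adv·L_adv + w_rec·L_rec + w_ω·Ω with
  default weights (4, 1e-2, 25, 1e-4).

Because all channels have equal length, "per channel then averaged"
MSEs equal plain means over all entries; the tests pin this equivalence
against naive loops.

**Estimating Ω.** The exact Jacobian of the full encoder (2048·15
outputs by 4·1920 inputs) is far too large to form. Three estimators
are provided: `exact` (one vector–Jacobian product per latent entry —
used in tests on sub-1000-parameter encoders, where it is validated
against central finite differences at 1e-4 relative tolerance),
`hutchinson` (Gaussian cotangent probes of E‖Jᵀv‖² = ‖J‖²_F), and `fd`,
the forward finite-difference directional estimator
‖f_E(x̂+εu) − f_E(x̂)‖²/ε² with u ~ N(0, I), also unbiased for ‖J‖²_F.
Training uses `fd` (ε = 1e-3): unlike the Hutchinson form, its weight
gradient needs only ordinary first-order backpropagation (two encoder
forwards), whereas differentiating ‖Jᵀv‖² with respect to the weights
would require a second-order (double-backward) pass. The whole-objective
gradient, including this term, is verified against finite differences
in the test suite.

**Discriminator update.** The discriminator's own loss is standard
binary cross-entropy (targets: 1 for clean windows, 0 for decoder
outputs, decoder detached), averaged so that a discriminator emitting
0.5 everywhere scores ln 2 per pair. One discriminator step follows
each generator step. The generator never receives gradients from the
discriminator's parameters update and vice versa; a test freezes each
optimizer in turn and verifies the other network's weights are
bit-identical through a full step.

## Training

Adam with decoupled weight decay (β = 0.9/0.999, ε = 1e-8), batch 8,
learning rate 1e-5, weight decay 5e-2, 20 epochs by default. Shuffling
uses a seeded generator; a fixed (config, seed) reproduces the loss
history exactly. If any loss turns non-finite the loop aborts and rolls
the model back to the end of the last completed epoch. Training runs in
float32; the gradient-check tests run in float64.

**Standardization frames.** Each window (clean or noisy) is
standardized by its own per-channel mean and standard deviation, with
the statistics stored. The network therefore maps noisy-standardized
input to clean-standardized output. Checkpoint evaluation computes
metrics in the standardized domain by default — there an identity model
has exactly zero SNR improvement, which pins the metric plumbing — and
in the physical domain (de-standardizing with the stored statistics) for
SNR numbers on the original scale. Whether standardization should be
per window or per record is a genuinely open choice; per window was
selected as the simplest convention that needs no record-level state at
inference.

**Desk-scale experiment.** The acceptance-scale run trains a
quarter-width model on 200 windows (four five-minute case0 records at
−6 dB, 250 Hz, resampled to 500 Hz → 78 windows each; the first 200
train, 50 of the remainder are held out) for 5 epochs with batch 8.
This sizing keeps the run at roughly two minutes on one CPU while still
showing the two properties that matter at this scale: the reconstruction
loss falls epoch over epoch, and held-out −6 dB windows gain several dB
of SNR. Headline-scale results (average improvements of tens of dB over
−30…0 dB inputs) require full-width training on a far larger simulated
corpus and are out of scope for the bundled experiments.

## Synthetic data generator

The simulator produces paired (clean fetal, noisy mixture) records with
the statistical structure the denoiser is meant for, not a biophysical
(volume-conductor) simulation.

* **Beat morphology**: each beat is a sum of five Gaussian components
  (P, Q, R, S, T) on a phase axis spanning one RR interval, in the
  spirit of the classical dynamical ECG model. Presets: `fetal`,
  `maternal` (slightly wider QRS, larger T), `ectopic` (≥1.5× wider and
  taller QRS, inverted T — a premature-ventricular-like shape). A small
  seeded jitter individualizes morphologies; per-channel polarity is
  random with at least one upright lead.
* **Rhythm**: fetal base rate uniform in 110–160 bpm, maternal in
  60–100 bpm (physiological ranges), 3 % Gaussian RR jitter.
* **Event cases**: `baseline` (maternal residue only), `case0` (+ white
  noise and sub-1 Hz baseline wander), `case1` (slow bounded sinusoidal
  per-channel gain drift — fetal movement), `case2` (a +20 bpm smooth
  rate ramp over 60 s — acceleration), `case3` (a 20–90 Hz noise burst
  covering 10–50 % of the record — uterine contraction EMG), `case4`
  (5 % premature ectopic beats with compensatory pauses). The exact
  spectral composition of each case is a documented stand-in; no public
  reference pins it.
* **Maternal interference**: synthesized at 2–10× the fetal amplitude,
  then attenuated to a 10 % residual, emulating an upstream maternal-ECG
  cancellation stage; ground-truth fetal and maternal R-peak indices are
  carried on the record.
* **SNR calibration**: the total interference is rescaled per channel so
  the input SNR 10·log10(Σx²/Σ(x̂−x)²) equals the requested value
  exactly (round-trip error < 1e-6 dB, tested across −30…+12 dB).
* Defaults: 4 channels, 300 s, 250 Hz, seeded and bit-reproducible.

What it does **not** emulate: realistic lead fields or electrode
geometry (it emits 4 channels directly rather than selecting 8 of 32),
twin pregnancies, fetal position changes, electrode pops, power-line
interference, or recording-device transfer functions. Passing tests on
this generator therefore demonstrate the pipeline's correctness and the
denoiser's behavior under controlled SNR — not clinical performance on
real abdominal recordings.

## Preprocessing

Maternal cancellation uses synchronized template subtraction: an
average beat per channel around the supplied maternal R peaks, removed
at each peak with a per-beat least-squares amplitude fit (which cannot
increase segment energy). A guard skips subtraction where the template
explains less than 5 % of segment energy (R² < 0.05), so spurious peak
lists leave a maternal-free record untouched. An extended-Kalman-filter
canceller can be plugged in behind the same interface. Resampling to
500 Hz is polyphase and anti-aliased; windows are non-overlapping
(overlap would be a training-augmentation option, not a default);
trailing remainders are dropped; indexing is 0-based throughout.

## Metrics

SNR_in/SNR_out/SNR_imp, RMSE and PRD follow the standard per-channel
definitions and are averaged arithmetically over channels. Exact
reconstruction returns a +∞ SNR sentinel (rather than raising) so batch
summaries stay computable; undefined detection ratios (zero
denominators) return an explicit None, never a silent zero.

QRS detection is a Hamilton-style adaptive-threshold detector:
8–30 Hz band-pass, derivative, squaring, 80 ms moving-average envelope,
peak picking with a 200 ms refractory period, and refinement of each
detection to the dominant local deflection. It is deliberately simple;
any external detector can be substituted, and no downstream computation
depends on its internals.

Peak matching against reference annotations uses a ±50 ms tolerance.
Because both sequences are sorted, a maximum-cardinality one-to-one
matching is always achievable without crossings, so it is computed
exactly by dynamic programming (tie-broken toward minimal total matched
distance) and verified in tests against brute-force optimal assignment.

## Wavelet baseline

Per-channel multilevel DWT with the sixth-order symlet, depth 6 at
500 Hz (deep enough that the approximation band sits below the QRS
band), soft thresholding of detail coefficients with per-level SURE
thresholds capped at the universal threshold, noise scale estimated
from the finest level via MAD/0.6745. The approximation band is not
thresholded. Without thresholding the filter bank reconstructs the
input to 1e-8, and soft thresholding never adds energy — both tested.

## Numerical and engineering notes

* All layers implement explicit forward/backward passes on numpy
  arrays; every gradient (per layer and through the whole composite
  objective) is validated against central finite differences.
* Layers are functional — `forward` returns an explicit cache — because
  the encoder participates in three concurrent forward passes per
  training step (noisy, clean, perturbed).
* Transposed convolution is implemented as the exact adjoint of the
  corresponding strided/dilated convolution; an inner-product test pins
  the adjoint identity.
* Checkpoints, window containers and reports are plain `.npz`/CSV with
  a JSON metadata blob; WFDB support is a minimal format-16
  reader/writer (gain/baseline scaling) sufficient for round trips.

## Known limitations

* The bundled experiments are desk-scale; no full-width, full-corpus
  training run ships with the package.
* The simulator's noise taxonomy is a stand-in; conclusions about real
  abdominal recordings require real data.
* The maternal canceller is template subtraction, not a Kalman
  smoother; residual morphology differs accordingly.
* Only 4-lead inputs are supported (the architecture's first and last
  layers are fixed to four channels).
* The QRS detector is tuned for clean-to-moderately-noisy fetal traces;
  at very low SNR its counts degrade and only the matching/score
  machinery remains detector-agnostic.
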