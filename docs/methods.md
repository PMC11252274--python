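# Methods

`vepdecode` implements a complete visual-decoding chain for low-density
(8-channel) EEG at desk scale: a generative model of visually evoked
responses stands in for real recordings, and every downstream stage —
quality control, single-trial classification, embedding extraction, and
diffusion-based stimulus reconstruction — runs against that model. This
note describes the models, the parameters that matter, and the choices
made where the design was genuinely open.

## Synthetic VEP sessions

A session presents `n_classes × images_per_class` stimuli (default
20 × 30 = 600) for 2 s each, separated by a 1 s uniform gray screen, at
250 Hz on eight occipito-parietal channels (PO8, O2, O1, PO7, PO3, POZ,
PO4, Pz). Onsets are therefore spaced exactly 750 samples apart and the
stimulus sequence spans 30 minutes.

Each class `c` owns an evoked template: a negative N1 lobe and a positive
P2 lobe, each a Gaussian-windowed bump,

    s_c(t) = A1_c · exp(−(t − τ1_c)² / 2σ1²) + A2_c · exp(−(t − τ2_c)² / 2σ2²),

with per-class latencies τ1 ∈ [85, 135] ms, τ2 = τ1 + [70, 110] ms,
amplitudes A1 < 0 < A2, widths σ1 = 22 ms, σ2 = 38 ms, and a per-class
spatial gain vector over the 8 channels (uniform in [0.3, 1.2]). Trials
jitter the latency (SD 5 ms) and amplitude (SD 10 %). Class identity is
thus carried jointly by timing, amplitude and topography — the features a
temporal-then-spatial convolutional classifier is built to exploit.

Background noise is the sum of three independent components per channel:
1/f (pink) noise synthesised by spectral shaping of white noise
(SD 4 µV), white sensor noise (SD 2 µV), and a fixed-phase 60 Hz mains
sinusoid (amplitude 1 µV). A single `snr` knob rescales all template
amplitudes so that the median |P2| peak equals `snr` times the total noise
SD (≈ 4.53 µV); `snr = 0` leaves pure noise. The default `snr = 2` is a
clean-but-realistic laboratory regime (evoked peaks ≈ 9 µV against ≈ 4.5 µV
background). Gray-screen intervals contain noise only, which is what
licenses their use as a stimulus-free null control.

What the generator does *not* emulate: volume conduction from a head
model, ocular/muscle artifacts with realistic morphology (artifacts are
injected as explicit NaN / flat / cloned-channel / burst fixtures),
inter-subject variability, and non-stationary drift. Passing tests
therefore demonstrate that the pipeline recovers structure *of the kind it
assumes*, not performance on real recordings.

Sessions round-trip through 16-bit EDF (1 s records, µV physical units,
symmetric per-channel ranges; quantisation error < range/65534). EDF has
no missing-value code, so NaN samples are stored as the reserved digital
value −32768 and restored on read; `mne.io.read_raw_edf` reads the same
files and is used as an independent oracle for the writer.

Stimulus images are parametric: each class is one of five silhouettes
(disc, ring, cross, square, diamond) in a class hue on a class-specific
gray background, with per-image position/size/hue jitter. Backgrounds
dominate luminance, so within-class luminance spread stays well below the
between-class spread — the low-level class coherence the surrogate metric
classifier relies on.

## Preprocessing

Fixed order, applied per session: (1) segment the *unfiltered* recording
into 500-sample epochs at each onset and compute the bad-trial mask;
(2) filter the *continuous* signal — 4th-order Butterworth high-pass
(1 Hz) and low-pass (95 Hz) plus an IIR notch (60 Hz, Q = 30), each
applied forward–backward for zero phase; (3) re-segment; (4) drop flagged
trials; (5) z-score each channel over all retained samples of the session
and clamp |z| > 20 at ±20.

Bad-trial criteria (computed on raw epochs): any non-finite sample
(`nan`); any channel with peak-to-peak < 0.01 µV (`flat`); any channel
pair with |Pearson r| > 0.99 (`corr_high`, a bridged or duplicated
electrode); mean over the 28 pairs of |r| < 0.02 (`corr_low`, a
disconnected channel). The `corr_low` default is set *below* the null
expectation of |r| for independent 500-sample channels,
E|r| = √(2/π(n−1)) ≈ 0.036, so that clean trials — even uncorrelated
white-noise ones — are never rejected; genuinely recorded trials share
evoked signal and line noise and sit far above it. All four thresholds are
configuration values.

One interaction needs care: a zero-phase IIR filter smears a single NaN
over its entire channel. Because the mask is computed before filtering,
`preprocess_session` zero-imputes NaN samples on a copy for the filtering
step only; the NaN trials themselves are dropped by the mask, and the
standalone `filter_raw` still propagates NaNs untouched.

## Classifier and encoder

The classifier is a compact three-block CNN: a temporal convolution
(64 filters of length 64 samples, 'same' padding), a depthwise spatial
convolution across all 8 electrodes (depth multiplier 2 → 128 maps), and a
separable convolution (depthwise 1×16 + pointwise 1×1), each followed by
batch normalisation and an exponential-linear activation, with max-pooling
(1×4 then 1×8) and dropout 0.25, ending in a linear layer over the
128 × 15 = 1920 flattened features. For 8 channels × 500 samples × 20
classes this totals exactly 62,612 trainable parameters
(4096 + 128 + 1024 + 256 + 2048 + 16384 + 256 + 38420), verified in the
tests against an independent closed-form accounting. Convolutions are
bias-free (batch norm supplies the offset); the classifier head carries a
bias. "64 temporal filters" is read as F1 = 64 with kernel length 64: with
depth multiplier 2 and pools (4, 8) this is the only reading that lands at
~62k parameters.

The embedding variant replaces the head with two linear layers,
1920 → 512 → n_classes; the 512-unit layer is the embedding `y` used to
condition the reconstruction model, and encoder mode simply drops the
final layer. No nonlinearity is inserted between the two head layers: the
backbone supplies the nonlinearity and a linear read-out leaves the
embedding unconstrained.

All networks run on a small reverse-mode autodiff engine written for this
package on numpy (`vepdecode.nn`): grouped/depthwise convolution via
im2col-style GEMMs with hand-written backward passes, batch/group norm,
ELU/SiLU, pooling, dropout, softmax/cross-entropy, AdamW, and a one-cycle
learning-rate schedule (cosine warm-up over the first 30 % of steps from
max_lr/25 to max_lr, cosine annealing to max_lr/10⁴). Every op's gradient
is checked against central differences in the test-suite. Weight decay is
applied only to matrices/kernels, never to biases or norm affines.

## Training protocol and evaluation

Training minimises cross-entropy with AdamW under one-cycle scheduling;
mini-batches are reshuffled each epoch from the run seed, and the weights
from the best-validation epoch are restored at the end. Per subject, the
recording with the fewest dropped trials is the hold-out test set (ties:
lowest session index), the next-fewest is validation, and the rest train;
a grid search, when used, picks the best validation accuracy (ties: fewer
parameters) and retrains on train + validation before the single test-set
evaluation. Leave-one-recording-out cross-validation over the non-test
recordings estimates the selection effect.

Model contrasts use the paired Wilcoxon signed-rank test (exact null for
n ≤ 25, zero differences dropped, one-sided where superiority is claimed)
with Bonferroni correction; the implementation is validated against
exhaustive enumeration of all 2ⁿ sign patterns. The point-biserial
correlation is computed from the group-difference formula and agrees with
the Pearson formula to 10⁻¹².

Desk-scale study sizes (all configurable): the classification-recovery
study simulates one subject with 12 sessions of 600 trials, trains for
4 one-cycle epochs at `snr = 2` (2 epochs at `snr = 0`, where nothing is
learnable) with batch 128 and max_lr 3·10⁻³. At these settings the
high-SNR subject tests above 90 % while the zero-SNR subject sits at the
5 % chance level — bracketing the claim that decoding rests on
stimulus-evoked structure, not on incidental temporal correlations.

## Reconstruction pathway

The image codec is a small convolutional autoencoder mapping 3×S×S images
to 4-channel latents at S/4 resolution (compression ×12; default desk
scale S = 32 → 4×8×8 latents). A vector-quantised variant (small codebook,
straight-through estimator) is available behind a config flag; the plain
codec is the default. Latents are rescaled to unit variance before
diffusion. A held-out MSE bound guards against a diverged codec.

The denoiser is a two-level UNet over latents (32 → 64 channels, one
downsampling) with residual blocks, group normalisation and SiLU.
Conditioning is double: (i) the 512-d embedding is reshaped into
M = 4 tokens of depth 128 and projected with a 1×1 convolution to
d_τ = 64-dimensional tokens that serve as keys and values in single-head
cross-attention — softmax(QKᵀ/√d_k)·V with Q from the feature map and
K, V from the tokens — at the coarse resolution and in the middle block;
(ii) a second projector flattens the tokens to a d_t = 64 vector added to
the sinusoidal time-step embedding. Disabling pathway (ii) recovers the
single-conditioning objective. The training objective is the standard
noise-prediction MSE ‖ε − ε_θ(z_t, t, τ(y), σ(τ(y)))‖².

The workflow mirrors transfer from a generatively pretrained model: the
UNet is first pretrained *conditionally in a separate conditioning
context* — each class owns a fixed random 512-d "prompt" vector, standing
in for the text conditioning of a generic pretrained LDM — and the EEG
fine-tuning then swaps encoder embeddings into that functional
conditioning pathway. Pretraining unconditionally instead leaves the
cross-attention weights without any learning signal: with a small,
effectively memorisable latent set, the noise-prediction loss gains
almost nothing from conditioning once the backbone alone can identify the
latent from z_t, so attention trained only during fine-tuning never
learns to steer. For the same reason the toy forward process uses a
linear β schedule from 10⁻⁴ to 2·10⁻² over T = 300 (not 1000) steps:
terminal ᾱ ≈ 0.05 keeps the whole trajectory inside the noise range where
conditioning measurably reduces the loss. Both choices are config fields
(`schedule_T`, pretraining embeddings).

Fine-tuning updates only the EEG encoder, the cross-attention weights
(W_Q, W_K, W_V and output projections) and the two projectors — the UNet
backbone and the codec stay bitwise frozen, a contract asserted in the
tests. Three numerical choices make the EEG-to-conditioning alignment
learnable on hundreds of pairs: embeddings are standardised per dimension
(statistics frozen from the fine-tuning pairs and re-applied at
inference), Gaussian noise (SD 0.5) is added to the standardised
embeddings during training so attention keys on class-level structure
rather than memorising trial vectors, and the encoder's own learning rate
is ~25× smaller than the attention/projector rate so its pretrained class
structure survives. The reference procedure's fine-tuning values
(learning rate 5·10⁻⁶, 200 epochs) are kept as constants in the config
module; the desk scale uses 5·10⁻⁴ (encoder 2·10⁻⁵) for 8 epochs.

Sampling is deterministic PLMS: a decreasing subsequence of the schedule
(25 steps at desk scale; 250-step, 256×256 operation is a config preset,
not exercised in tests), a two-evaluation pseudo-Heun first step, then
2nd/3rd-order Adams–Bashforth forms until four noise evaluations are
buffered, then the 4th-order combination (55e − 59e₁ + 37e₂ − 9e₃)/24.
For a denoiser whose output ignores z_t the whole trajectory collapses to
a closed form, which the tests exploit as an oracle. An optional
predicted-x₀ clip bounds the implied clean latent during each transfer —
at very small ᾱ the 1/√ᾱ division amplifies model error, and a small
denoiser's trajectory can otherwise leave the data scale entirely.

Evaluation follows the n-way top-1 protocol: a small surrogate CNN
classifier trained on the stimulus set scores each generated image; per
trial, n−1 distractor classes are drawn without replacement and the
reconstruction counts as correct if the true class outranks all of them.
The desk-scale metric uses n = 10 of the 20 stimulus classes (chance
10 %) with 1000 Monte-Carlo trials per image and five samples per EEG
trial (distinct seeds): drawing fewer distractors than there are classes
keeps per-sample accuracies graded rather than 0/1, which matters for the
aggregates below. The report carries both the best-of-5 and mean-of-5
accuracies.

The null control feeds the 1 s gray-screen segments — upsampled to 500
samples (linear interpolation by default, Fourier resampling as a flag),
channel-wise z-scored, then passed through the same standardisation —
through the identical encoder → sampler → metric chain; its labels are
the class of the preceding stimulus, which is independent of the
segment's content, so the *expected per-sample* accuracy is exactly
chance. Note that best-of-k is an order statistic: even for a completely
stimulus-independent system its expectation exceeds chance (for a 0/1
per-sample metric it approaches k·chance), so "the null sits at chance"
is asserted on the mean-over-samples aggregate, where the expectation is
exactly 1/n. The stimulus-dependence property is then two-sided: real
trials must exceed chance by ≥ 5 standard errors on best-of-5 and must
beat the null control on both aggregates, while the null's mean stays
within 3 standard errors of chance.

## Numerical and engineering notes

* Determinism: every stochastic element (noise synthesis, shuffling,
  dropout, initialisation, distractor draws, sampling) derives from an
  explicit `numpy` Generator seeded by the caller; identical seeds give
  bit-identical results on a fixed platform.
* float32 is used for network training; float64 for signal processing and
  statistics. Batch-norm running statistics accumulate in float64.
* Max-pool drops the trailing remainder of the time axis (500 → 125 → 15),
  matching the flattened feature count behind the 62,612 total.
* Degenerate inputs fail loudly: zero-SD channels at normalisation,
  empty splits, windows past the end of a recording, non-integer sample
  spacing, attention dimension mismatches.
* Problem sizes in the tests and the reproduction script (12×600-trial
  classification subject; 4×500-trial reconstruction subject, 32×32
  stimuli, 100 test images) were chosen so the whole suite runs on a
  single CPU core in tens of minutes; all are dataclass fields that scale
  up without code changes.

## Known limitations

The synthetic generator's class separation is optimistic (stationary
templates, independent noise across channels), so absolute accuracies do
not transfer to real EEG. The diffusion model is a toy: at 32×32 with a
~300k-parameter UNet it demonstrates the conditioning mechanics and the
stimulus-dependence contrast, not photorealistic reconstruction. The
unseen-class (zero-shot) regime is not an acceptance surface and is only
reachable by configuring disjoint stimulus sets manually.
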