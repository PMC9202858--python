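# Methods

## Scope and design

`somnostage` implements a 5-class (W, S1, S2, S3, REM) sleep stager for
single-channel (configurable multichannel) EEG: a multi-scale residual
convolutional encoder with channel and spatial attention per epoch, a
bidirectional GRU over sequences of consecutive epochs, label-smoothed
cross-entropy training, and an evaluation surface of confusion matrix,
per-stage recall, overall recognition rate, Cohen's kappa and
recording-grouped cross-validation. A synthetic polysomnography generator
makes every stage of the pipeline testable offline.

All tensor computation runs on the package's own numpy reverse-mode
autodiff engine (`_engine.py`): a tape of closures over im2col/BLAS
convolutions, pooling, batch normalisation, pointwise nonlinearities and a
fused softmax cross-entropy. Analytic gradients are verified against
central finite differences in float64 in the test suite; training runs in
float32.

## Data model and preprocessing

Recordings are read from EDF (via `mne`) in microvolts and cut into
non-overlapping 30-s epochs starting at sample 0 — no lights-off trimming,
so segmentation is deterministic and dataset-independent. Hypnogram row
`i` annotates samples `[i·30·fs, (i+1)·30·fs)`, half-open. Annotation
vocabularies for both R&K and AASM dialects map onto the five classes, with
R&K S4 merged into S3 (slow-wave sleep); movement-time and unscored
annotations become EXCLUDED and are dropped with a logged count before
training or evaluation; unknown strings raise rather than being silently
discarded. The only signal preprocessing is per-epoch, per-channel
z-scoring (on by default, flag to disable); no filtering or artifact
rejection is applied, which keeps the pipeline's behaviour attributable to
the model rather than to preprocessing choices.

The internal epoch store is a single HDF5 file (data, labels, fs,
epoch_seconds, source_id); hypnograms import/export as two-column CSV.

## The synthetic generator

The generator emulates what the stager needs from real sleep EEG and
nothing more:

* **Stage-specific spectra.** Each stage renders amplitude-modulated
  random-phase sinusoids over Gaussian background noise: W → alpha
  (8–12 Hz, ~30 µV) with a weak beta component; S1 → theta (4–7 Hz);
  S2 → theta plus 12–14 Hz spindle bursts (1-s Hann-windowed events,
  per-second occurrence probability 0.35); S3 → high-amplitude delta
  (0.5–2 Hz, ~75 µV); REM → low-amplitude mixed theta/beta. Amplitudes
  are in the range of real scalp EEG; a 1/f noise-shaping flag exists but
  defaults off so periodogram peaks sit unambiguously in the principal
  bands.
* **Hypnogram dynamics.** Labels follow a first-order Markov chain started
  at W with transition matrix `P = 0.85·I + 0.15·1π^T`. This form was
  chosen over hand-spread "adjacent stage" mass because it satisfies both
  desiderata at once: self-transition ≥ 0.85 (mean bout ≥ ~7 epochs
  ≈ 3.5 min, sleep-bout persistence) and stationary distribution exactly π.
  π defaults to the expert-scored Sleep-EDF proportions
  (18.90/6.68/42.43/13.59/18.40 %), reproducing the S2:S1 ≈ 6:1 imbalance
  regime. Any row-stochastic matrix may be substituted.
* **Determinism.** A night is generated from a `SeedSequence` spawned per
  epoch, so the same seed gives bit-identical nights.

What the generator does *not* emulate: stage-transition waveforms
(K-complexes at S2 onset), artifacts (EMG, eye blinks, electrode pops),
inter-subject variability, or non-stationarity across the night. Passing
tests on synthetic data therefore demonstrate that the implementation
learns and evaluates correctly on class-separable spectral data — they are
not evidence of clinical-grade accuracy on real polysomnography, whose
headline numbers require the real datasets and full-scale training.

The separability itself is a tested property: a logistic regression on
per-epoch relative band powers reaches ≥ 90 % 5-class accuracy, so the
downstream deep model's end-to-end results are meaningful rather than
vacuous.

The EDF fixture writer is hand-written (plain EDF, 1-s records, 16-bit,
symmetric physical range); since reading goes through `mne`, the round-trip
test cross-checks two independent codepaths to within one quantisation
step.

## Architecture choices

Where the design was genuinely open, the package resolves it as follows:

* **Attention placement.** CAU then SAU on the residual branch output,
  before the shortcut addition (the CBAM convention; the channel-attended
  map is the input the spatial unit expects). A bypass switch forces unit
  gates, which is tested to reproduce the plain residual block exactly.
* **Channel-attention MLP.** Hidden width `ceil(C/r)` with floor 1,
  default reduction r = 16; shared weights between the avg- and max-pooled
  paths; ReLU at the bottleneck; no biases. The second MLP weight is
  transposed relative to the first so the composition type-checks.
* **Spatial attention in 1-D.** The classical 7×7 image kernel becomes a
  width-7 convolution over the 2-row channel-mean/max map (padding 3, one
  output row).
* **Stem and downsampling.** Stem conv width 7, stride 2, then 1×3 max
  pool stride 2. Each stage's first block downsamples with stride 2 and a
  1×1 strided projection (+BN) on the shortcut. One block per stage by
  default (configurable). Inputs shorter than `2^(2+n_stages)` samples are
  rejected with the minimum in the message — below that, stride-2 steps
  would convolve over padding only.
* **Per-scale output.** Global average pooling (one value per feature
  map), giving exactly a 512-vector per branch at the full-size widths;
  the three scales are concatenated (not summed) to preserve them,
  yielding the 1536-wide sequence feature.
* **Activation.** ReLU inside the blocks by default, with a SELU switch,
  since both appear in descriptions of this architecture family.
* **Recurrent head.** The BiGRU consumes the *inter-epoch* sequence of
  fused vectors (default 10 consecutive epochs; the scaled-down profile
  uses 5) — the reading under which it models dependence between sleep
  stages. Hidden size 128 per direction by default; dropout 0.5 before
  the dense head. Both directions start from zero states; per-step output
  is the concatenation of the two states.

The residual identities hold exactly and are tested: a zero branch makes
the block the identity on its (non-negative) input domain, zero attention
pre-activations gate uniformly at sigmoid(0) = 0.5, and composing
identity-shortcut blocks without the outer nonlinearity equals the shallow
feature plus the explicitly accumulated branch outputs.

## Training

Targets are smoothed one-hot rows (`1 − ε` at the true class, `ε/(k−1)`
elsewhere; ε defaults to 0.1, and smoothing never changes the target
argmax for ε < (k−1)/k). The loss is mean cross-entropy against these rows;
at ε = 0 it equals standard cross-entropy to machine precision.

The optimizer is Adam with β₁ = 0.9, β₂ = 0.999, eps = 1e-8; the default
recipe uses learning rate 0.005, weight-decay ratio 0.1 and batch size 16,
with 200 passes. Weight decay is **decoupled** (AdamW-style) by default:
coupling a 0.1 decay through Adam's preconditioner makes the effective
decay step erratic; a flag restores coupled L2 for comparison. Batches are
windows of `sequence_length` consecutive epochs from one recording;
shuffling permutes windows, never epochs within a window. The
best-validation state is retained and restored at the end; early stopping
exists but is off by default. Training is deterministic under the config
seed (weight init, shuffling and dropout all derive from seeded
generators); a NaN loss aborts with a diagnostic rather than training on.

The scaled-down profile used throughout the tests and the acceptance
script — stage widths 8/16/32/64, BiGRU hidden 16, 5-epoch sequences,
learning rate 1e-3, decoupled decay 1e-4, 20 passes on a 2000-epoch night —
was chosen as a problem size a laptop CPU handles in minutes while leaving
the architecture structurally identical to the full-size recipe. On the
default synthetic conditions it reaches high-90s accuracy and κ close to 1
on held-out nights; an untrained model sits at chance and a constant-S2
baseline at the S2 prevalence with κ exactly 0.

## Evaluation

Confusion rows are expert (true) stages, columns predictions, order
W, S1, S2, S3, REM. Per-stage recall is diagonal over row sum with empty
rows reported as NaN, never silently 0. Kappa is computed as
(p₀ − p_e)/(1 − p_e) with p_e from the marginal products; the degenerate
single-cell matrix (p_e = 1) raises. A test cross-checks the
implementation against a pairwise brute-force computation and against
scikit-learn on random label sets.

Cross-validation folds group by recording by default (no subject
contributes to both train and test); an epoch-level mode mimics the weaker
protocol. Spread is the sample (n−1) standard deviation, formatted
`mean±sd` to 2 decimals.

## Numerical notes and limitations

* float32 training; gradient checks run the same graph in float64.
* Max pooling and the channel-max descriptor route gradients to the first
  argmax on ties.
* Batch-norm batch statistics couple samples in training mode; the batch
  permutation-equivariance property is therefore stated (and tested) in
  evaluation mode, which uses running statistics.
* Rounded percentages (2 decimals) over five classes can sum to
  100 ± 0.025 in the worst case; the tests use this exact bound.
* The CLI covers `simulate`, `train`, `evaluate`, `stage` and `run`; all
  artifacts embed the hash of the scientific config (output directory and
  log level excluded) plus the seed, and re-running with both reproduces
  the report byte-identically.
* Single-channel EEG only by default; EOG/EMG fusion, resampling,
  artifact rejection and clinical summaries (sleep efficiency, latency)
  are out of scope.
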