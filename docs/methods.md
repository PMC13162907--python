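# Methods

This note documents the modeling, numerical and design choices in
`pigvoc`, in the spirit of a model-documentation page: what is computed,
under which assumptions, which knobs matter, and what the synthetic test
substrate does and does not show.

## Input pipeline

All clips pass one shared pipeline: resample to 16 kHz
(polyphase), peak-normalize (peak rather than RMS normalization; the
choice only fixes an arbitrary gain that per-clip standardization removes
again later), extract an 80-band log-Mel spectrogram with 25 ms frames
and 10 ms hop over 0–8 kHz, trim leading/trailing silence, and
(optionally) apply spectral gating.

Numerical conventions, chosen to be analytically checkable:

- **Framing**: no center padding; a clip of `N` samples yields
  `T = 1 + floor((N − 400)/160)` frames. FFT size 512 (next power of two
  above the 400-sample window), periodic Hann window.
- **Mel filterbank**: HTK mel scale, triangular filters with unit-area
  (Slaney-style) normalization so a spectrally flat input produces a flat
  mel profile; without it, band estimates are biased toward the wide
  high-frequency filters.
- **Log scale**: values are `10·log10(power + 1e-10)` dB; the additive
  floor keeps all-zero input finite at exactly `−100` dB.
- **Silence trimming**: a frame is silent when its total energy is more
  than 40 dB below the loudest frame (config-exposed). Trimming is
  slice-only — retained values are never altered — and residual
  low-energy *interior* frames are flagged in the frame mask consumed by
  masked pooling. Clips that are silent throughout raise an
  empty-segment error so callers can drop them.
- **Spectral gating**: per mel band the noise floor is the 20th
  percentile of the band's frame values; each cell gets gain
  `g = g_min + (1−g_min)·σ((v − floor − 3 dB) · 1/dB)` applied to the
  linear amplitude (`+20·log10 g` dB). Defaults: `g_min = 0.1`, offset
  3 dB, unit slope. `g_min = 1` is the exact identity, which is how the
  no-gating ablation behaves. The operation is deterministic and
  identical at training and inference time.

## Network

Shapes: `(F=80, T)` input → Conv2d(3×3, C′ channels)–BatchNorm–ReLU–
AvgPool(2×2) → `(C′, 40, T/2)` → triplet attention → per-time-step
flatten + linear projection to `D` → sinusoidal positional encoding →
`n_blocks` encoder blocks → masked attentive pooling → cosine
classification head.

- **Triplet attention** uses the reference design for each of the three
  rotated views: Z-pool (concatenated max- and mean-pooling over the
  remaining axis), a 7×7 convolution, and a sigmoid gate; the three gated
  branches are averaged. The layer accepts explicit override gates as a
  diagnostic hook, which the tests use to verify the fusion rule
  (unit gates → identity; gates (1,1,0) → 2/3 of the input).
- **Decoupled encoder block**: pre-LayerNorm input feeds (a) multi-head
  self-attention over time with masked frames excluded as keys (−1e9
  additive bias before the softmax) and (b) a k-tap convolution along the
  feature axis of each frame (frequency content lives in the flattened
  channel dimension after projection, so "frequency-local" is
  feature-local; one shared kernel, no cross-time mixing). The branches
  are concatenated and fused by a single FFN (expansion 4, SiLU,
  dropout), wrapped in a residual connection and a closing LayerNorm.
  Whether a decoupled block should retain both Conformer half-step FFNs
  is an open design point; a single fused FFN was chosen for parsimony.
- **Symmetric baseline block** (the "without decoupling" ablation): a
  standard Conformer block — half-step FFN, MHSA, convolution module
  (pointwise → GLU → depthwise-in-time → SiLU → pointwise), half-step
  FFN, final LayerNorm.
- **Masked attentive pooling** computes the attention weights only over
  valid frames (masked frames get −1e9 logits), making the mask
  multiplication in `z = Σ m α h / (Σ m α + ε)` exact: the content of a
  masked frame cannot change `z` at all. `ε = 1e-8`. The frame mask is
  computed at input resolution and max-pooled by the front end's factor
  of 2 so it aligns with encoder frames.
- **Classification head**: L2-normalized embedding against L2-normalized
  class weights; training applies the additive angular margin to the true
  class with `θ_y + m` clamped to `[0, π]` (the `arccos` argument is
  clipped away from ±1 by a dtype-dependent epsilon for a finite
  gradient); inference scores are `softmax(s·cosθ)`.

Defaults (config-exposed): `C′ = 32`, `D = 128`, 4 heads, 2 blocks,
`k = 15`, dropout 0.1, `s = 30`, `m = 0.2` rad. The positional encoding
can be disabled, which makes the encoder block exactly
permutation-equivariant — a property the tests exploit.

## Training

Adam (β = 0.9/0.999), initial learning rate 0.001, batch size 16, up to
100 epochs, fixed seed 42 by default. Model selection is the best
validation Macro-F1 (ties broken by the earliest epoch); learning rate is
halved after 5 epochs without improvement and training stops after 15
(both config-exposed; the underlying schedule in the original protocol is
not specified beyond "scheduling and early stopping"). Splits are
verified for group/pig exclusivity before the first epoch; a violating
split aborts. Variable-length clips are zero-padded per batch with their
frame masks zeroed, so padding is excluded from attention keys and
pooling. Determinism is guaranteed only single-process, single-thread
CPU; all randomness (initialization, batch order, dropout) derives from
the run seed.

The numerical backend is a package-local reverse-mode autograd over
NumPy (float32 in the training path; float64 when callers pass float64,
which the functional loss/pooling entry points use). Gradients of every
layer are verified against central finite differences in the test suite.

## Evaluation protocols

- **Group tokens**: routine clips → (pen, date, session); close-range
  cough clips → one token per pig (all of a pig's directed recordings
  stay in one subset); estrus clips use their breeding-stall session
  token. Group-to-partition allocation is a deterministic greedy pass
  over seeded-shuffled, size-ordered groups, assigning each group to the
  partition with the largest remaining per-class deficit; sample ratios
  are therefore approximate by construction.
- **LOSO**: the held-out session defines the test set; the grouped
  train/val subdivision happens only within the remaining sessions. A
  pig's close-range clips can span sessions, so for LOSO the session rule
  takes precedence and exclusivity is asserted within the development
  partitions.
- **Metrics**: accuracy, per-class precision TP/(TP+FP), recall
  TP/(TP+FN), F1, one-vs-rest AUROC; macro = unweighted mean. (One
  published formula line repeats the recall denominator for precision;
  the surrounding text makes clear standard precision is meant, which is
  what is implemented.) A class absent from the ground truth is excluded
  from macro averages with a warning rather than scored 0/0. Reported
  confusion percentages are row-normalized and rounded to one decimal.
- **Wilcoxon**: exact two-sided signed-rank distribution (scipy's exact
  method), zero differences dropped with a warning. Note that for n = 5
  paired folds the smallest attainable two-sided p is 0.0625; smaller
  printed values in the source analysis cannot come from this exact test.
- **Noise sweep**: each test clip is mixed with a noise-pool segment
  whose group token differs from the clip's (raising an error otherwise),
  at exact SNRs; default bins +10/+5/0/−5 dB. No retraining or threshold
  recalibration.

## Synthetic barn generator

The generator is the test substrate replacing farm recordings. Class
recipes are constrained by the published acoustic profiles (dominant
band, mean duration) and qualitative descriptions, not calibrated to the
real recordings:

| class | band (kHz) | mean dur (s) | envelope |
|---|---|---|---|
| cough | 0.8–3.0 | 1.82 | 1–3 decaying broadband bursts |
| scream | 3.0–8.0 | 1.75 | sustained + vibrato harmonic core |
| estrus | 1.0–3.5 | 1.94 | Hann pulse train at 3 Hz |
| feeding | 0.2–2.5 | 1.88 | slow amplitude-modulated rough noise |
| normal | 0–1.5 | 1.80 | ambient low-pass noise + 100 Hz hum |

Events are band-passed white noise (4th-order Butterworth) shaped by the
envelope family and mixed over a quiet background (low-passed noise +
hum) at a class-specific event SNR (15/18/10/8/3 dB). Group structure:
5 finishing pens × 4 dates × 3 sessions; estrus clips come from 3
separate breeding stalls; 74% of coughs are close-range recordings of 5
symptomatic pigs (the complement of the reported 26% routine share).
The noon session carries the domain shift: background +3 dB *and* event
SNR −3 dB (an absolute gain alone would vanish under per-clip
normalization). The magnitude was chosen once so that session effects
are statistically detectable but small — on the scale of one or two
macro-F1 points — keeping LOSO tests meaningful. Everything regenerates
bit-identically from (config, seed); waveforms are derived from
per-sample seed sequences.

What passing tests on this substrate do **not** show: robustness to
reverberation, overlapping events, device/channel variation, or the true
within-class variability of farm recordings — none of which the
generator models. Synthetic results validate the machinery (shapes,
losses, leakage protocols, optimization, ordering of ablations), not
field performance.

## Study sizes used by the automated checks

The automated end-to-end checks run a compact configuration chosen as a
package default for desk-scale experiments: encoder width `D = 64`, two
encoder blocks, 16 front-end channels, and short optimization budgets
(5–6 epochs, which this substrate saturates; the synthetic classes are
near-separable and validation Macro-F1 plateaus within a few epochs).
Grouped 5-fold cross-validation runs on the default 500-clip dataset
(seed 42); the ablation-direction and noise-sweep checks use a 150-clip
dataset. Larger configurations are available through the same configs.

## Known limitations

- The spectral-gating hyperparameters, triplet-attention internals and
  AAM settings are conventional defaults where the source protocol left
  them unstated; all are config-exposed.
- BatchNorm statistics in training mode include padded frames of a
  batch; masks keep padding out of attention and pooling, and inference
  uses running statistics, so per-clip predictions are padding-exact
  only at inference.
- The exact signed-rank test is implemented as described; it cannot
  reproduce p-values below its combinatorial minimum for five folds.
- Real-data accuracy figures are not reproducible without the farm
  dataset and are out of scope here.
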