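# Methods

## Problem setting

Automatic sleep-stage classification assigns one of the five AASM stages
— wake (W), N1, N2, N3 and REM — to every 30-second epoch of an
overnight EEG recording. The constraint addressed here is deployment:
the classifier must fit and run on a generic microcontroller, which
bounds the weight budget (< 100 KB) far below what mainstream sleep
stagers use. The package implements a compact classifier family built
for that budget, together with the architecture search that motivates
its design and the int8 quantization path that achieves it.

All signal processing assumes single-channel EEG resampled to 100 Hz and
cut into 3000-sample epochs; recordings scored under the six-stage R&K
standard are mapped onto the AASM vocabulary with N4 merged into N3, and
MOVEMENT/UNKNOWN epochs are excluded rather than relabelled.

## Model

The epoch classifier is a shallow residual CNN over depthwise-separable
convolutions:

* **start block** — normal convolution (64 filters, kernel 32), batch
  norm before the ReLU, then max pooling (4);
* **conv block** — depthwise-separable convolution (64 filters, kernel
  16; batch norm before each activation) summed with a pointwise-conv
  projection of the block input, then average pooling (4);
* **identity block** — the same separable branch summed with the raw
  block input (channel count preserved, no pooling);
* global average pooling and a 5-way softmax head.

Block-level choices (normal conv with a large kernel first, separable
convolutions after; max pooling early, average pooling late; the
64-filter / kernel-32 caps) follow the preferences the constrained
architecture search exhibits. The exact per-block filter and kernel
numbers are not uniquely determined by the search description, so the
pinned instance above was fixed once to respect the caps and land the
total budget at 0.02 M parameters (23 818 trainable scalars); the spec
is YAML-configurable so alternatives are one file edit.

A decoupled sequence learner exploits the fact that sleep stages form
long bouts: stage transitions between adjacent epochs are rare and
structured. It reads the CNN's softmax vector for 12 consecutive epochs
(a trailing window predicting the last epoch; the leading edge of each
recording is padded by repeating the first epoch's probabilities, and
windows never cross recordings) through LSTM(32) → dropout(0.2) →
Dense(32, ReLU) → dropout(0.2) → softmax. Keeping the sequence stage
separate from the CNN keeps its input 12×5 instead of a raw-signal
window, which is what makes its parameter cost (6 085 scalars)
negligible.

Inputs are standardized per epoch (zero mean, unit variance over the
3000 samples) at the model boundary; this makes differently calibrated
recordings and the synthetic generator commensurable and removes
amplitude as a shortcut feature. Biases are kept in every convolution
(cheap at this scale).

### Numerical core

No deep-learning framework is used: all layers (1-D convolution,
depthwise convolution, batch norm, pooling, LSTM, dense, dropout), their
analytic backward passes, and the Adam/SGD optimizers are implemented
directly in numpy (float32). Convolutions run as one im2col GEMM when
the window tensor is small enough and as kernel-shifted matmul
accumulation otherwise; batch norm at inference is folded into a single
affine. Every backward pass is verified against central finite
differences in the test suite. Batch-norm uses momentum 0.9 and eps
1e-5; running statistics are buffers, not trainable parameters, and are
excluded from the parameter count (at deployment they fold into the
batch-norm affine).

## Training

Two stages, both Adam (β₁ = 0.9, β₂ = 0.999), categorical cross-entropy,
subject-disjoint train/validation/test splits, and best-validation-
accuracy checkpointing:

1. CNN: lr 1e-3, batch 128, 10 passes.
2. Sequence learner on the frozen CNN's probability windows: lr 1e-4,
   batch 32; the pass count is configurable (default 10). A runtime
   assertion confirms stage two never touches CNN weights.

The cross-validation harness splits by subject (k-fold or
leave-one-out), holds out 10 % of each fold's training subjects for
validation, and reports per-fold metrics plus a pooled report from the
summed confusion matrix (pooling over epochs rather than averaging over
folds; both are available). Metrics are accuracy, macro-F1, macro
sensitivity (mean per-class recall) and macro specificity (mean
per-class one-vs-rest specificity), all in percent; classes absent from
the truth are excluded from macro averages with a warning. No class
weighting is applied by default.

## Architecture search

The search is a deliberately simplified DARTS: each cell has one node
whose output is a softmax(α)-weighted sum of candidate operations,
Y = Σₖ softmax(α)ₖ·oₖ(X). Architecture weights α and operation weights θ
are updated *jointly* — one gradient step for both from a single loss
evaluation per batch, same optimizer (Adam, lr 1e-3), no separate
validation split — making the search a single optimization problem
rather than a bi-level one. The macro network is fixed at four
convolutional cells (candidates: normal vs depthwise-separable
convolution at kernels {16, 32}, 64 filters) and two reduction cells
(max vs average pooling, size 4), and the search covers feature
extraction only (no sequence stage). The final architecture keeps the
argmax-softmax(α) candidate per cell; ties break to the lowest candidate
index with a warning. Softmax normalization of the mixture (rather than
a raw weighted sum) keeps the weights comparable across cells and the
argmax meaningful.

The planted-recovery experiment packaged in `nas.planted_recovery_search`
validates the mechanism: a frozen quadrature matched-filter front end
turns a two-tone classification task into band channels; a mixed cell
then chooses between a depthwise-separable smoothing operation frozen at
the exactly-sufficient band-envelope computation and a channel-collapsing
competitor of the same form and scale that erases class identity. The
planted operation's mixture weight must rise; 1500 updates at lr 1e-3
give the α gap (Adam steps are bounded by the learning rate) room to
clear softmax weight 0.6 with margin.

## Quantization

Weights are quantized per tensor to int8 with an asymmetric affine map:
scale = (max − min)/255 over the tensor's range (nudged to include
zero), zero-point chosen so the minimum maps to −128. Only CNN
convolution/dense weights and biases are quantized; batch-norm
parameters and the sequence learner stay float32. A quantization plan
names the included blocks, so the variant that exempts the start and
identity blocks — which recovers accuracy on harder data — is one set
difference.

Fine-tuning is quantization-aware with a straight-through estimator:
each step evaluates the network at fake-quantized weights and applies
the gradients to float shadow weights, re-quantizing per step; after 5
such passes (batch 128, lr 1e-3) the CNN is frozen at its int8 values
and the float sequence learner is re-fitted for 5 passes (batch 32,
lr 1e-3). Whether the original recipe used full QAT or post-training
quantization plus float fine-tuning of the rest is not specified; the
STE approach is this package's declared choice, and plain post-training
quantization is available for contrast.

The byte budget counts 1 byte per quantized weight plus 8 bytes per
quantized tensor (float32 scale + int32 zero-point) and 4 bytes per
remaining float parameter. The flat binary written by
`model.save_flat_binary` contains exactly these bytes (its JSON manifest
is metadata, not payload), so the file size equals
`estimate_size_bytes` bit-exactly: 43.07 KB fully quantized, 64.6 KB
with start+identity exempt, 93.0 KB float — all under the 100 KB cap,
with the fully quantized model under 50 KB. Raw float weights of a
0.02 M-parameter model are ~93 KB; larger on-disk figures for float
checkpoints are serialization overhead of the training framework and
are not part of the budget.

## Synthetic data

The generator provides stage-dependent EEG so the whole pipeline is
trainable and testable without downloads. Each stage is narrow-band
oscillations on 1/f broadband noise (spectrally shaped white noise):
alpha (10 Hz) in W with a high-noise floor, theta (6 Hz) in N1, theta
plus 11–16 Hz spindle bursts (0.5–1 s Hann-windowed, ~4 per epoch) and
occasional K-complex transients in N2, high-amplitude 0.5–2 Hz delta in
N3, and low-amplitude mixed theta/beta in REM. Amplitudes are in µV
with stage-typical magnitudes (e.g. 80 µV delta vs 8 µV REM theta);
exact values are package defaults chosen once for class separability
comparable to what scorers rely on, not fits to any dataset.

Hypnograms come from a first-order Markov chain at 30-s resolution with
strongly diagonal transitions (self-transition ≥ 0.85) and
physiologically ordered off-diagonals (W→N1→N2→{N3, REM}, arousals back
to W/N1). The diagonal dominance is what makes temporal context
genuinely informative, so the sequence learner's benefit is testable.
Seeding is hierarchical (master seed → per-subject → per-epoch via
numpy SeedSequence), so datasets are reproducible and subjects
independent.

What the generator does **not** contain: artifacts, EMG/EOG
contamination, electrode drift, inter-subject spectral variability,
stage-transition nonstationarity within a night. Passing tests on this
data certify the pipeline's mechanics (learnable spectra, context
benefit, quantization robustness), not clinical performance; real-data
accuracy must be measured with the CV harness on real PSG corpora.

## Scaled-down study sizes

The standing synthetic benchmark uses 6 subjects (4 train / 1
validation / 1 test) × 120 epochs — roughly an eighth of a real night
per subject — chosen as the package's repeatable desk-scale experiment.
At this size the CNN recipe keeps its exact settings; the sequence
learner keeps lr 1e-4 / batch 32 but runs 600 passes over the small
window set so its total gradient-step count matches what 10 passes over
full-night corpora would provide. Quantized fine-tunes keep their
5-pass recipe. The evaluation-window trimming modes (±30 min = 60
epochs per side; in-bed = first to last non-wake epoch) follow the
community convention of the baselines whose splits the CV harness
mirrors.

## Known limitations

* Pure-numpy training is CPU-bound; full-night corpora are feasible but
  slow compared to framework implementations.
* Per-tensor (not per-channel) quantization is deliberate — smaller
  manifests, simpler MCU kernels — and costs some accuracy headroom.
* Activation quantization, integer-only inference kernels and
  deployment-format export are out of scope; the flat binary is a
  weight budget audit, not a runtime format.
* The EDF writer targets single-channel fixtures (16-bit, 1-s records)
  and does not emit EDF+ annotation streams; hypnograms travel as CSV
  sidecars.
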