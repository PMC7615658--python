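# morpheusnet

Resource-efficient sleep-stage classification from single-channel EEG,
built for embedded targets: a ~0.02 M-parameter residual
depthwise-separable CNN scores 30-second epochs into the five AASM
stages (W, N1, N2, N3, REM), a decoupled LSTM re-reads the CNN's class
probabilities over 12-epoch windows to exploit sleep's bout structure,
and an int8 quantization path with quantized fine-tuning brings the
deployable weight budget under 50 KB — comfortably inside the < 100 KB
footprint a generic microcontroller allows. The package also implements
the constrained single-level differentiable architecture search
(mixed-operation cells, jointly optimized architecture weights α and
model weights θ) that motivates the block design.

Intended users: researchers prototyping on-device sleep staging or
closed-loop sleep therapies (e.g. targeted memory reactivation), who
need strict parameter/byte accounting and a fully reproducible pipeline
that runs without any dataset download.

## Model in brief

Epoch classifier (input: one 30-s epoch, 3000 × 1 at 100 Hz,
standardized per epoch):

    start:    Conv(64, k=32) → BN → ReLU → MaxPool(4)
    conv:     [DWConv(k=16) → BN → ReLU → PWConv(64) → BN → ReLU] + PWConv(input) → AvgPool(4)
    identity: [DWConv(k=16) → BN → ReLU → PWConv(64) → BN → ReLU] + input
    head:     GlobalAvgPool → Dense(5) → softmax

Sequence learner (input: CNN softmax vectors of 12 consecutive epochs):

    LSTM(32) → Dropout(0.2) → Dense(32, ReLU) → Dropout(0.2) → Dense(5) → softmax

Training is two-stage (Adam 1e-3 / batch 128 / 10 epochs for the CNN,
then Adam 1e-4 / batch 32 on the frozen CNN's probability windows),
with best-validation-accuracy checkpointing and subject-disjoint
splits. Quantization is per-tensor asymmetric affine int8 of the CNN
weights only, fine-tuned for 5 epochs with a straight-through
estimator; a plan can exempt blocks (e.g. start + identity). See
`docs/methods.md` for the full account.

The neural-network layers, their backward passes and the optimizers are
implemented directly in numpy and verified against finite differences;
there is no deep-learning-framework dependency.

## Worked example

```python
from morpheusnet.model import default_spec, build_model, count_parameters, estimate_size_bytes
from morpheusnet.quant import QuantizationPlan
from morpheusnet.experiments import run_benchmark_seed

model = build_model(default_spec(), seed=0)
print(f"trainable parameters: {count_parameters(model, 'total'):,} "
      f"({count_parameters(model, 'total') / 1e6:.2f} M)")
print(f"float32 weight budget: {estimate_size_bytes(model) / 1024:.1f} KB")
plan = QuantizationPlan.full(model)
print(f"int8 weight budget:    {estimate_size_bytes(model, plan) / 1024:.1f} KB")

result = run_benchmark_seed(seed=0)   # full synthetic pipeline, ~3 min on CPU
print(f"held-out accuracy: CNN alone {result.cnn_accuracy:.1%}, "
      f"+sequence learner {result.seq_accuracy:.1%}, "
      f"int8 fine-tuned {result.quant_accuracy:.1%}")
```

prints

```
trainable parameters: 23,818 (0.02 M)
float32 weight budget: 93.0 KB
int8 weight budget:    43.1 KB
held-out accuracy: CNN alone 92.5%, +sequence learner 93.3%, int8 fine-tuned 96.7%
```

The first three lines are the size accounting: 23 818 trainable scalars
(0.02 M), four bytes each in float32, one byte each for quantized CNN
weights plus an 8-byte scale/zero-point per tensor (batch norm and the
sequence learner stay float32). The last line is a complete scaled-down
study on synthetic data (4 training subjects, one validation, one
held-out; 120 epochs each): the sequence learner improves on per-epoch
CNN classification by exploiting stage-transition structure, and the
quantized, fine-tuned model loses nothing at this scale.

## Command line

```sh
morpheus synth --subjects 3 --epochs 100 --seed 7 --out fixtures/   # EDF + hypnogram CSVs
morpheus nas --steps 200 --out nas_out/        # search; emits derived YAML + α-trajectory CSV
morpheus train --config run.yaml --out run/    # two-stage training + evaluation JSON
morpheus cv --config run.yaml --k 5            # subject-wise cross-validation
morpheus quantize --config run.yaml --exclude start,identity
morpheus report run/                           # metrics table, params, footprint PASS/FAIL
```

Real PSG corpora (EDF recordings with hypnograms, e.g. Sleep-EDF) are
supported through the same config (`data.edf_dir`, `data.channel`,
`data.trim: pm30|in_bed|none`); they require separate download and are
not needed by the test suite.

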