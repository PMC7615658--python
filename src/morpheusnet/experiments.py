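"""Standing synthetic-benchmark experiments shared by tests and scripts.

One "benchmark seed" is a complete scaled-down study on synthetic sleep
data: generate subjects, train the CNN with the standard recipe, train
the sequence learner on its probability windows, quantize the CNN to
int8, run both fine-tunes, and evaluate everything on a held-out
subject.  All randomness derives from the single seed.

Problem sizes: 6 subjects (4 train / 1 validation / 1 test) with 120
30-second epochs each — a deliberately scaled-down stand-in for full
overnight recordings (~1000 epochs per night).  The sequence learner
keeps the standard optimizer recipe (Adam, lr 1e-4, batch 32) but makes
correspondingly more passes over the small window set so its gradient-step
count is comparable to a full-scale run.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import synthetic
from .model import BuiltModel, default_spec
from .quant import QuantizationPlan, apply_plan, default_finetune_config, finetune_quantized
from .train import (
    StageConfig,
    TrainConfig,
    predict_sequence,
    stack_epochs,
    train_two_stage,
)

N_SUBJECTS = 6
N_TRAIN, N_VAL, N_TEST = 4, 1, 1
EPOCHS_PER_SUBJECT = 120
SEQ_PASSES = 600  # passes over the scaled-down window set


def benchmark_train_config(seed: int) -> TrainConfig:
    return TrainConfig(
        cnn=StageConfig(lr=1e-3, batch_size=128, epochs=10),
        seq=StageConfig(lr=1e-4, batch_size=32, epochs=SEQ_PASSES),
        seed=seed,
    )


def benchmark_dataset(seed: int):
    recs = synthetic.generate_dataset(N_SUBJECTS, EPOCHS_PER_SUBJECT, seed)
    return recs[:N_TRAIN], recs[N_TRAIN : N_TRAIN + N_VAL], recs[N_TRAIN + N_VAL :]


@dataclass
class BenchmarkResult:
    """Held-out accuracies (fractions) for one benchmark seed."""

    cnn_accuracy: float
    seq_accuracy: float
    quant_accuracy: float
    quant_no_finetune_accuracy: float
    model: BuiltModel


def _epoch_accuracy(model: BuiltModel, recs) -> float:
    X, y = stack_epochs(recs)
    return float((model.cnn.predict(X) == y).mean())


def _seq_accuracy(model: BuiltModel, recs) -> float:
    hits = total = 0
    for r in recs:
        hits += int((predict_sequence(model, r) == r.labels).sum())
        total += r.n_epochs
    return hits / total


def run_benchmark_seed(seed: int, with_quant: bool = True) -> BenchmarkResult:
    """Full two-stage training (+ optional int8 path) on one seed's data."""
    train_recs, val_recs, test_recs = benchmark_dataset(seed)
    cfg = benchmark_train_config(seed)
    model = train_two_stage(default_spec(), train_recs, val_recs, cfg)
    cnn_acc = _epoch_accuracy(model, test_recs)
    seq_acc = _seq_accuracy(model, test_recs)
    if not with_quant:
        return BenchmarkResult(cnn_acc, seq_acc, float("nan"), float("nan"), model)

    # post-training quantization without fine-tuning, for the paired contrast
    from .model import build_model

    ptq = build_model(default_spec(), seed=seed)
    ptq.cnn.load_state_dict(model.cnn.clone_state())
    ptq.seq.load_state_dict(model.seq.clone_state())
    plan = QuantizationPlan.full(ptq)
    apply_plan(ptq, plan)
    ptq_acc = _seq_accuracy(ptq, test_recs)

    plan = QuantizationPlan.full(model)
    finetune_quantized(model, plan, train_recs, val_recs, default_finetune_config(seed))
    quant_acc = _seq_accuracy(model, test_recs)
    model.cnn.net.free_caches()
    model.seq.net.free_caches()
    return BenchmarkResult(cnn_acc, seq_acc, quant_acc, ptq_acc, model)
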