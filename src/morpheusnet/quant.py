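"""8-bit weight quantization of the CNN with quantized fine-tuning.

Weights are quantized per tensor with an asymmetric affine int8 scheme:
``scale = (max - min) / 255``, ``zero_point`` placed so the tensor's
minimum maps to -128.  The sequence learner is never quantized; a
quantization plan may additionally exempt named CNN blocks — exempting
the start and identity blocks is the variant that recovers accuracy on
harder datasets.

Fine-tuning treats the rounding step as identity for gradients
(straight-through estimator): each step evaluates the network at the
fake-quantized weights, applies the resulting gradients to the float
shadow weights, and re-quantizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import BuiltModel
from .train import StageConfig, TrainConfig, _fit, build_sequence_dataset, one_hot, stack_epochs


@dataclass
class QuantizedTensor:
    q: np.ndarray  # int8
    scale: float
    zero_point: int

    def dequantize(self) -> np.ndarray:
        return (self.q.astype(np.float32) - self.zero_point) * np.float32(self.scale)


def quantize_tensor(x: np.ndarray) -> QuantizedTensor:
    """Asymmetric per-tensor affine quantization to int8."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot quantize an empty tensor")
    if not np.all(np.isfinite(x)):
        raise ValueError("tensor contains NaN/Inf")
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        # the representable range is nudged to include zero so the
        # zero-point always fits in int8 (no-op for weight tensors, which
        # straddle zero anyway)
        lo, hi = min(lo, 0.0), max(hi, 0.0)
        scale = (hi - lo) / 255.0
        zero_point = int(np.clip(np.round(-128.0 - lo / scale), -128, 127))
    else:
        # constant tensor: unit scale unless the constant itself is outside
        # the int8 span, in which case the scale grows to keep it exact
        scale = max(1.0, abs(hi) / 127.0)
        zero_point = int(np.clip(np.round(-hi / scale), -128, 127))
    q = np.clip(np.round(x / scale) + zero_point, -128, 127).astype(np.int8)
    return QuantizedTensor(q=q, scale=scale, zero_point=zero_point)


def fake_quantize(x: np.ndarray) -> np.ndarray:
    """Quantize then dequantize; the value the int8 deployment would see."""
    return quantize_tensor(x).dequantize()


@dataclass
class QuantizationPlan:
    """Which CNN blocks get int8 weights; the rest stay float32."""

    included_blocks: set[str]
    excluded_blocks: set[str] = field(default_factory=set)
    bit_width: int = 8

    @classmethod
    def full(cls, model: BuiltModel) -> "QuantizationPlan":
        return cls(included_blocks=set(model.block_names), excluded_blocks=set())

    @classmethod
    def excluding(cls, model: BuiltModel, kinds: set[str]) -> "QuantizationPlan":
        """Exempt blocks whose name starts with any of the given kinds
        (e.g. ``{"start", "identity"}`` for the starred variant)."""
        excl = {n for n in model.block_names if any(n.startswith(k) for k in kinds)}
        return cls(included_blocks=set(model.block_names) - excl, excluded_blocks=excl)

    def validate(self, model: BuiltModel) -> None:
        names = set(model.block_names)
        unknown = (self.included_blocks | self.excluded_blocks) - names
        if unknown:
            raise ValueError(f"plan references unknown blocks: {sorted(unknown)}")
        if self.included_blocks | self.excluded_blocks != names:
            missing = names - self.included_blocks - self.excluded_blocks
            raise ValueError(f"plan does not cover blocks: {sorted(missing)}")


def _quantized_params(model: BuiltModel, plan: QuantizationPlan):
    """Yield (layer, name, array) for every tensor the plan quantizes."""
    blocks = model.named_blocks()
    for bname in sorted(plan.included_blocks):
        for lyr in blocks[bname].iter_layers():
            for pname in lyr.params:
                if pname in lyr.quantizable:
                    yield bname, lyr, pname, lyr.params[pname]


def apply_plan(model: BuiltModel, plan: QuantizationPlan) -> dict:
    """Replace included blocks' weights by their fake-quantized values.

    Returns a manifest mapping tensor ids to (scale, zero_point).
    """
    plan.validate(model)
    manifest = {}
    for bname, lyr, pname, p in _quantized_params(model, plan):
        qt = quantize_tensor(p)
        p[...] = qt.dequantize()
        manifest[f"{bname}/{type(lyr).__name__}/{pname}"] = {
            "scale": qt.scale,
            "zero_point": qt.zero_point,
        }
    return manifest


def default_finetune_config(seed: int = 0) -> TrainConfig:
    """5-epoch fine-tunes: CNN at batch 128, sequence learner at batch 32,
    both with Adam at learning rate 1e-3."""
    return TrainConfig(
        cnn=StageConfig(lr=1e-3, batch_size=128, epochs=5),
        seq=StageConfig(lr=1e-3, batch_size=32, epochs=5),
        seed=seed,
    )


def finetune_quantized(model: BuiltModel, plan: QuantizationPlan, train_recs, val_recs, cfg: TrainConfig | None = None) -> dict:
    """Quantization-aware fine-tuning, then sequence-learner re-fit.

    Stage 1 fine-tunes the CNN with the straight-through estimator: the
    forward/backward pass runs at fake-quantized weights, the update is
    applied to the float shadow weights.  Stage 2 re-fits the (float)
    sequence learner on the quantized CNN's probability windows; the
    CNN's int8 weights stay fixed.  Returns the final quantization
    manifest.
    """
    plan.validate(model)
    cfg = cfg or default_finetune_config()
    X, y = stack_epochs(train_recs)
    Xv, yv = stack_epochs(val_recs)
    Y = one_hot(y)
    rng = np.random.default_rng(cfg.seed + 2)
    opt = nn.Adam(lr=cfg.cnn.lr, beta1=cfg.cnn.beta1, beta2=cfg.cnn.beta2)
    qparams = list(_quantized_params(model, plan))
    clf = model.cnn
    for _ in range(cfg.cnn.epochs):
        order = rng.permutation(len(X))
        for i in range(0, len(X), cfg.cnn.batch_size):
            idx = order[i : i + cfg.cnn.batch_size]
            shadows = [p.copy() for *_ignored, p in qparams]
            for *_ignored, p in qparams:
                p[...] = fake_quantize(p)
            xb = clf._prep(X[idx])
            logits = clf.net.forward(xb, training=True)
            probs = nn.softmax(logits)
            if not np.isfinite(probs).all():
                raise FloatingPointError("non-finite values in quantized fine-tuning")
            clf.net.backward((probs - Y[idx]) / len(idx))
            for (*_ignored, p), shadow in zip(qparams, shadows):
                p[...] = shadow  # STE: apply the update to the float shadow
            opt.step(clf.net)
    # freeze the CNN at its deployable int8 values
    manifest = apply_plan(model, plan)
    cnn_snapshot = [p.copy() for *_ignored, p in qparams]

    seq_rng = np.random.default_rng(cfg.seed + 3)
    Xs, ys = build_sequence_dataset(clf, train_recs, model.spec.sequence.context_len)
    Xvs, yvs = build_sequence_dataset(clf, val_recs, model.spec.sequence.context_len)
    _fit(model.seq, Xs, ys, Xvs, yvs, cfg.seq, seq_rng)
    for (*_ignored, p), snap in zip(qparams, cnn_snapshot):
        assert np.array_equal(p, snap), "sequence fine-tune moved quantized CNN weights"
    return manifest
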