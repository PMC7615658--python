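"""MorpheusNet model construction and strict size accounting.

The CNN is a shallow residual network over depthwise-separable
convolutions, built from three block types:

* **start block** — normal convolution -> batch norm -> ReLU -> max pool;
* **conv block** — depthwise-separable convolution (batch norm before each
  activation) summed with a pointwise-convolution residual, then a pool;
* **identity block** — depthwise-separable convolution summed with the
  unmodified input (channel count preserved).

A global average pool and a softmax dense layer map features to the five
sleep stages.  A decoupled sequence learner — LSTM(32) -> dropout(0.2) ->
Dense(32, ReLU) -> dropout(0.2) -> softmax — reads the CNN's class
probabilities over a trailing window of 12 epochs and re-predicts the last
epoch, exploiting stage-transition structure.

Every trainable scalar is accounted for exactly, so parameter counts and
int8/float32 byte budgets can be audited against a hardware memory cap.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .data_io import EPOCH_SAMPLES, N_CLASSES

MAX_FILTERS = 64
MAX_KERNEL = 32


@dataclass
class BlockSpec:
    kind: str  # start | conv | identity
    filters: int = MAX_FILTERS
    kernel: int = 16
    pool: str = "none"  # max | avg | none
    pool_size: int = 1

    def __post_init__(self):
        if self.kind not in ("start", "conv", "identity"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.filters > MAX_FILTERS:
            raise ValueError(f"filters {self.filters} exceeds the search-space cap {MAX_FILTERS}")
        if self.kernel > MAX_KERNEL:
            raise ValueError(f"kernel {self.kernel} exceeds the search-space cap {MAX_KERNEL}")
        if self.pool not in ("max", "avg", "none"):
            raise ValueError(f"unknown pool {self.pool!r}")


@dataclass
class SequenceSpec:
    context_len: int = 12
    lstm_units: int = 32
    dense_units: int = 32
    dropout_rate: float = 0.2

    def __post_init__(self):
        if self.context_len < 1:
            raise ValueError("context_len must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0,1)")


@dataclass
class ArchitectureSpec:
    """Declarative description of the CNN blocks plus the sequence learner."""

    blocks: list[BlockSpec]
    sequence: SequenceSpec = field(default_factory=SequenceSpec)
    input_len: int = EPOCH_SAMPLES
    n_classes: int = N_CLASSES

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("at least one block required")
        # identity blocks must preserve channel count
        c = 1
        for b in self.blocks:
            if b.kind == "identity" and b.filters != c:
                raise ValueError(
                    f"identity block requires {c} filters to preserve channels, got {b.filters}"
                )
            c = b.filters

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "input_len": self.input_len,
            "n_classes": self.n_classes,
            "blocks": [vars(b).copy() for b in self.blocks],
            "sequence": vars(self.sequence).copy(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            blocks=[BlockSpec(**b) for b in d["blocks"]],
            sequence=SequenceSpec(**d.get("sequence", {})),
            input_len=d.get("input_len", EPOCH_SAMPLES),
            n_classes=d.get("n_classes", N_CLASSES),
        )

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "ArchitectureSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_spec() -> ArchitectureSpec:
    """The pinned MorpheusNet instance (~0.02 M parameters total).

    Normal convolution with the largest allowed kernel first, separable
    convolutions after; max pooling early, average pooling late — the
    operation pattern the architecture search prefers — at the 64-filter /
    kernel-32 caps of the search space.
    """
    return ArchitectureSpec(
        blocks=[
            BlockSpec("start", filters=64, kernel=32, pool="max", pool_size=4),
            BlockSpec("conv", filters=64, kernel=16, pool="avg", pool_size=4),
            BlockSpec("identity", filters=64, kernel=16),
        ]
    )


# ---------------------------------------------------------------------------
# Blocks as composite layers
# ---------------------------------------------------------------------------

def _pool_layer(pool: str, size: int) -> nn.Layer | None:
    if pool == "none" or size <= 1:
        return None
    return nn.MaxPool1D(size) if pool == "max" else nn.AvgPool1D(size)


class StartBlock(nn.Sequential):
    def __init__(self, c_in: int, spec: BlockSpec, rng):
        layers = [
            nn.Conv1D(c_in, spec.filters, spec.kernel, rng),
            nn.BatchNorm1D(spec.filters),
            nn.ReLU(),
        ]
        pool = _pool_layer(spec.pool, spec.pool_size)
        if pool is not None:
            layers.append(pool)
        super().__init__(layers)


class _ResidualBlock(nn.Layer):
    """Separable-conv branch plus a residual path, summed, then pooled."""

    def __init__(self, branch: nn.Sequential, residual: nn.Layer | None, pool: nn.Layer | None):
        super().__init__()
        self.branch = branch
        self.residual = residual  # None = identity shortcut
        self.pool = pool

    def forward(self, x, training=False):
        y = self.branch.forward(x, training=training)
        r = x if self.residual is None else self.residual.forward(x, training=training)
        out = y + r
        if self.pool is not None:
            out = self.pool.forward(out, training=training)
        return out

    def backward(self, dy):
        if self.pool is not None:
            dy = self.pool.backward(dy)
        dx = self.branch.backward(dy)
        dx = dx + (dy if self.residual is None else self.residual.backward(dy))
        return dx

    def iter_layers(self):
        yield from self.branch.iter_layers()
        if self.residual is not None:
            yield from self.residual.iter_layers()
        if self.pool is not None:
            yield from self.pool.iter_layers()


def _separable_branch(c_in: int, c_out: int, kernel: int, rng) -> nn.Sequential:
    """Depthwise then pointwise convolution, batch norm before each ReLU."""
    return nn.Sequential(
        [
            nn.DepthwiseConv1D(c_in, kernel, rng),
            nn.BatchNorm1D(c_in),
            nn.ReLU(),
            nn.Conv1D(c_in, c_out, 1, rng),
            nn.BatchNorm1D(c_out),
            nn.ReLU(),
        ]
    )


class ConvBlock(_ResidualBlock):
    def __init__(self, c_in: int, spec: BlockSpec, rng):
        super().__init__(
            branch=_separable_branch(c_in, spec.filters, spec.kernel, rng),
            residual=nn.Conv1D(c_in, spec.filters, 1, rng),
            pool=_pool_layer(spec.pool, spec.pool_size),
        )


class IdentityBlock(_ResidualBlock):
    def __init__(self, c_in: int, spec: BlockSpec, rng):
        if spec.filters != c_in:
            raise ValueError("identity block must preserve the channel count")
        super().__init__(
            branch=_separable_branch(c_in, c_in, spec.kernel, rng),
            residual=None,
            pool=_pool_layer(spec.pool, spec.pool_size),
        )


_BLOCK_BUILDERS = {"start": StartBlock, "conv": ConvBlock, "identity": IdentityBlock}


@dataclass
class BuiltModel:
    """Built CNN + sequence learner with named CNN blocks for quantization."""

    cnn: nn.Classifier
    seq: nn.Classifier
    spec: ArchitectureSpec
    block_names: list[str]  # aligned with cnn.net.layers

    def named_blocks(self) -> dict[str, nn.Layer]:
        return dict(zip(self.block_names, self.cnn.net.layers))


def build_cnn(spec: ArchitectureSpec, rng: np.random.Generator) -> tuple[nn.Classifier, list[str]]:
    """Epoch classifier: blocks -> global average pool -> softmax dense."""
    layers: list[nn.Layer] = []
    names: list[str] = []
    counts: dict[str, int] = {}
    c = 1
    for b in spec.blocks:
        layers.append(_BLOCK_BUILDERS[b.kind](c, b, rng))
        counts[b.kind] = counts.get(b.kind, 0) + 1
        names.append(f"{b.kind}{counts[b.kind] if b.kind != 'start' else ''}" or b.kind)
        c = b.filters
    layers.append(nn.GlobalAvgPool1D())
    names.append("gap")
    layers.append(nn.Dense(c, spec.n_classes, rng))
    names.append("head")
    return nn.Classifier(nn.Sequential(layers), standardize=True), names


def build_sequence_model(spec: ArchitectureSpec, rng: np.random.Generator) -> nn.Classifier:
    """LSTM(32) over the window of per-epoch class probabilities."""
    s = spec.sequence
    drop_rng = np.random.default_rng(rng.integers(2**31))
    net = nn.Sequential(
        [
            nn.LSTM(spec.n_classes, s.lstm_units, rng),
            nn.Dropout(s.dropout_rate, drop_rng),
            nn.Dense(s.lstm_units, s.dense_units, rng),
            nn.ReLU(),
            nn.Dropout(s.dropout_rate, drop_rng),
            nn.Dense(s.dense_units, spec.n_classes, rng),
        ]
    )
    return nn.Classifier(net, standardize=False)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> BuiltModel:
    rng = np.random.default_rng(seed)
    cnn, names = build_cnn(spec, rng)
    seq = build_sequence_model(spec, rng)
    return BuiltModel(cnn=cnn, seq=seq, spec=spec, block_names=names)


# ---------------------------------------------------------------------------
# Size accounting
# ---------------------------------------------------------------------------

def count_parameters(model: BuiltModel, part: str = "total") -> int:
    """Exact count of trainable scalars in the CNN, sequence learner or both."""
    if part == "cnn":
        return model.cnn.net.n_params()
    if part == "seq":
        return model.seq.net.n_params()
    if part == "total":
        return model.cnn.net.n_params() + model.seq.net.n_params()
    raise ValueError(f"unknown part {part!r}")


def output_lengths(spec: ArchitectureSpec) -> list[int]:
    """Closed-form temporal length after each block (floor-division pooling)."""
    lengths = []
    L = spec.input_len
    for b in spec.blocks:
        if b.pool != "none" and b.pool_size > 1:
            L = L // b.pool_size
        lengths.append(L)
    return lengths


def _block_tensors(block: nn.Layer, quantized: bool):
    """Yield (param_array, is_quantizable) over a block's tensors."""
    for lyr in block.iter_layers():
        for name, p in lyr.params.items():
            yield p, quantized and name in lyr.quantizable


def estimate_size_bytes(model: BuiltModel, plan=None) -> int:
    """Deployment weight budget in bytes.

    Quantized tensors cost 1 byte per weight plus 8 bytes for their
    float32 scale and int32 zero-point; everything else (batch-norm
    parameters, excluded blocks, the sequence learner) costs 4 bytes per
    float32 scalar.
    """
    included = set() if plan is None else set(plan.included_blocks)
    total = 0
    for name, block in model.named_blocks().items():
        for p, q in _block_tensors(block, name in included):
            total += p.size + 8 if q else 4 * p.size
    total += 4 * model.seq.net.n_params()
    return total


# ---------------------------------------------------------------------------
# Portable flat binary (ordered tensors + JSON manifest)
# ---------------------------------------------------------------------------

def save_flat_binary(model: BuiltModel, path: str | Path, plan=None) -> dict:
    """Write weights as a flat binary audited bit-exactly by
    :func:`estimate_size_bytes`; the JSON manifest sits in a sidecar file.

    Quantized tensors are stored as int8 payload + float32 scale + int32
    zero-point; float tensors as raw float32.  Batch-norm running
    statistics are folded into the stored scale/shift (as a deployment
    would), so the file holds exactly the trainable scalars.
    """
    from .quant import quantize_tensor  # local import to avoid a cycle

    included = set() if plan is None else set(plan.included_blocks)
    path = Path(path)
    manifest = {"tensors": []}
    buf = io.BytesIO()
    offset = 0

    def emit(owner: str, lyr_idx: int, name: str, p: np.ndarray, quantized: bool):
        nonlocal offset
        entry = {
            "block": owner,
            "layer": lyr_idx,
            "name": name,
            "shape": list(p.shape),
            "offset": offset,
        }
        if quantized:
            qt = quantize_tensor(p)
            buf.write(np.float32(qt.scale).tobytes())
            buf.write(np.int32(qt.zero_point).tobytes())
            buf.write(qt.q.astype(np.int8).tobytes())
            entry.update(dtype="int8", scale=float(qt.scale), zero_point=int(qt.zero_point))
            offset += 8 + p.size
        else:
            buf.write(p.astype(np.float32).tobytes())
            entry["dtype"] = "float32"
            offset += 4 * p.size
        manifest["tensors"].append(entry)

    def folded(lyr, pname, p):
        if isinstance(lyr, nn.BatchNorm1D):
            inv = 1.0 / np.sqrt(lyr.running_var + lyr.eps)
            a = lyr.params["gamma"] * inv
            return a if pname == "gamma" else lyr.params["beta"] - lyr.running_mean * a
        return p

    for bname, block in model.named_blocks().items():
        for i, lyr in enumerate(block.iter_layers()):
            for pname, p in lyr.params.items():
                emit(bname, i, pname, folded(lyr, pname, p), bname in included and pname in lyr.quantizable)
    for i, lyr in enumerate(model.seq.net.iter_layers()):
        for pname, p in lyr.params.items():
            emit("sequence", i, pname, folded(lyr, pname, p), False)

    path.write_bytes(buf.getvalue())
    manifest["total_bytes"] = offset
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_flat_binary(model: BuiltModel, path: str | Path) -> None:
    """Restore weights written by :func:`save_flat_binary` into ``model``.

    Quantized tensors are dequantized on load (the model keeps float32
    arrays); the architecture must match the manifest tensor for tensor.
    Batch-norm scale/shift arrive pre-folded, so running statistics are
    reset to the identity; the loaded model is for inference, not for
    continued training.
    """
    path = Path(path)
    manifest = json.loads(Path(str(path) + ".json").read_text())
    blob = path.read_bytes()
    blocks = model.named_blocks()

    def target(entry):
        owner = entry["block"]
        layers = list(
            model.seq.net.iter_layers() if owner == "sequence" else blocks[owner].iter_layers()
        )
        return layers[entry["layer"]].params[entry["name"]]

    for entry in manifest["tensors"]:
        p = target(entry)
        n = int(np.prod(entry["shape"])) if entry["shape"] else 1
        off = entry["offset"]
        if entry["dtype"] == "int8":
            scale = np.frombuffer(blob, np.float32, 1, off)[0]
            zp = np.frombuffer(blob, np.int32, 1, off + 4)[0]
            q = np.frombuffer(blob, np.int8, n, off + 8)
            p[...] = ((q.astype(np.float32) - zp) * scale).reshape(entry["shape"])
        else:
            p[...] = np.frombuffer(blob, np.float32, n, off).reshape(entry["shape"])
    for clf in (model.cnn, model.seq):
        for lyr in clf.net.iter_layers():
            if isinstance(lyr, nn.BatchNorm1D):
                lyr.running_mean[...] = 0.0
                lyr.running_var[...] = 1.0 - lyr.eps
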