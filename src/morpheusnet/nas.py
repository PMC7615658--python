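"""Single-level differentiable architecture search over a macro network.

Each cell holds one node whose output is a softmax(α)-weighted sum of its
candidate operations: Y = Σ_k softmax(α)_k · o_k(X).  Unlike bi-level
DARTS, architecture weights α and operation weights θ are updated
simultaneously by one gradient step on one categorical cross-entropy
evaluation per batch — a single optimization problem with a shared
learning rate and no separate validation split for α.

The searched macro-architecture is fixed: four convolutional cells
(candidates: normal vs depthwise-separable convolutions at kernels up to
32 and at most 64 filters) and two reduction cells (max vs average
pooling).  The final architecture keeps the argmax-softmax(α) candidate
of every cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import ArchitectureSpec, BlockSpec, _separable_branch


class MixedCell(nn.Layer):
    """One-node cell mixing candidate operations by softmax(α)."""

    def __init__(self, kind: str, candidates: list[tuple[str, nn.Layer]]):
        super().__init__()
        if len(candidates) < 1:
            raise ValueError("a mixed cell needs at least one candidate")
        self.kind = kind
        self.names = [n for n, _ in candidates]
        self.candidates = [op for _, op in candidates]
        self.params["alpha"] = np.zeros(len(candidates), dtype=np.float32)

    def weights(self) -> np.ndarray:
        return nn.softmax(self.params["alpha"])

    def forward(self, x, training=False):
        ys = [op.forward(x, training=training) for op in self.candidates]
        shapes = {y.shape for y in ys}
        if len(shapes) > 1:
            raise ValueError(f"candidate output shapes differ: {shapes}")
        w = self.weights()
        self._ys, self._w = ys, w
        return sum(wk * yk for wk, yk in zip(w, ys))

    def backward(self, dy):
        w, ys = self._w, self._ys
        g = np.array([float((dy * yk).sum()) for yk in ys])
        self.grads["alpha"] = (w * (g - float(w @ g))).astype(np.float32)
        dx = None
        for wk, op in zip(w, self.candidates):
            d = op.backward(wk * dy)
            dx = d if dx is None else dx + d
        return dx

    def iter_layers(self):
        yield self
        for op in self.candidates:
            yield from op.iter_layers()


def _normal_candidate(c_in, filters, kernel, rng):
    return nn.Sequential([nn.Conv1D(c_in, filters, kernel, rng), nn.BatchNorm1D(filters), nn.ReLU()])


def conv_cell(c_in: int, filters: int, kernels: tuple[int, ...], rng) -> MixedCell:
    cands = []
    for k in kernels:
        cands.append((f"normal_k{k}", _normal_candidate(c_in, filters, k, rng)))
    for k in kernels:
        cands.append((f"separable_k{k}", _separable_branch(c_in, filters, k, rng)))
    cell = MixedCell("conv", cands)
    cell.filters = filters
    cell.kernels = kernels
    return cell


def reduction_cell(pool_size: int = 4) -> MixedCell:
    return MixedCell(
        "reduction",
        [(f"max{pool_size}", nn.MaxPool1D(pool_size)), (f"avg{pool_size}", nn.AvgPool1D(pool_size))],
    )


@dataclass
class SearchState:
    """Mixed-operation network plus bookkeeping of the joint optimization."""

    net: nn.Classifier
    cells: list[MixedCell]
    optimizer: object
    loss_history: list[float] = field(default_factory=list)
    alpha_history: list[list[np.ndarray]] = field(default_factory=list)
    loss_evals: int = 0

    def record(self):
        self.alpha_history.append([c.weights().copy() for c in self.cells])


def build_search_state(
    seed: int = 0,
    n_classes: int = 5,
    filters: int = 64,
    kernels: tuple[int, ...] = (16, 32),
    pool_size: int = 4,
    lr: float = 1e-3,
    optimizer: str = "adam",
    layout: str = "ccrccr",
) -> SearchState:
    """Macro search network: conv (c) and reduction (r) cells per `layout`,
    then global average pooling and a softmax head.

    The default layout has four conv and two reduction cells; candidates
    respect the 64-filter / kernel-32 search-space caps.
    """
    if filters > 64 or max(kernels) > 32:
        raise ValueError("search space caps: filters <= 64, kernel <= 32")
    rng = np.random.default_rng(seed)
    cells: list[MixedCell] = []
    c = 1
    for ch in layout:
        if ch == "c":
            cells.append(conv_cell(c, filters, kernels, rng))
            c = filters
        elif ch == "r":
            cells.append(reduction_cell(pool_size))
        else:
            raise ValueError(f"layout characters must be 'c' or 'r', got {ch!r}")
    net = nn.Sequential([*cells, nn.GlobalAvgPool1D(), nn.Dense(c, n_classes, rng)])
    opt = nn.Adam(lr=lr) if optimizer == "adam" else nn.SGD(lr=lr)
    return SearchState(net=nn.Classifier(net, standardize=True), cells=cells, optimizer=opt)


def joint_update(state: SearchState, X: np.ndarray, y_onehot: np.ndarray) -> SearchState:
    """One simultaneous gradient step on α and θ from a single loss evaluation."""
    if len(X) == 0:
        raise ValueError("empty batch")
    clf = state.net
    x = clf._prep(X)
    logits = clf.net.forward(x, training=True)
    probs = nn.softmax(logits)
    loss = nn.cross_entropy(probs, y_onehot)
    state.loss_evals += 1
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite search loss: {loss}")
    clf.net.backward((probs - y_onehot) / len(x))
    state.optimizer.step(clf.net)
    state.loss_history.append(loss)
    state.record()
    return state


def run_search(state: SearchState, X, y, batch_size: int, steps: int, seed: int = 0) -> SearchState:
    """Mini-batch joint optimization for a fixed number of update steps."""
    from .train import one_hot

    rng = np.random.default_rng(seed)
    n = len(X)
    for _ in range(steps):
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        joint_update(state, X[idx], one_hot(y[idx]))
    return state


def derive_architecture(state: SearchState) -> ArchitectureSpec:
    """Argmax-softmax(α) per cell; ties keep the lowest candidate index.

    Conv-cell winners become blocks (normal convolution -> start-style
    block; separable convolution -> residual conv block, or an identity
    block when the channel count is preserved); each reduction-cell winner
    becomes the pooling of the preceding conv block.
    """
    blocks: list[BlockSpec] = []
    c_in = 1
    for cell in state.cells:
        w = cell.weights()
        best = int(np.argmax(w))
        if np.sum(np.isclose(w, w[best], rtol=0, atol=1e-9)) > 1:
            warnings.warn(
                f"alpha tie in {cell.kind} cell; keeping lowest-index candidate "
                f"{cell.names[best]!r}"
            )
        name = cell.names[best]
        if cell.kind == "conv":
            kernel = int(name.rsplit("k", 1)[1])
            if name.startswith("normal"):
                kind = "start"
            elif cell.filters == c_in:
                kind = "identity"
            else:
                kind = "conv"
            blocks.append(BlockSpec(kind, filters=cell.filters, kernel=kernel))
            c_in = cell.filters
        else:
            pool = "max" if name.startswith("max") else "avg"
            size = int(name[3:])
            if not blocks:
                raise ValueError("reduction cell before any conv cell")
            blocks[-1].pool, blocks[-1].pool_size = pool, size
    return ArchitectureSpec(blocks=blocks)


def count_operations(spec: ArchitectureSpec) -> tuple[int, int]:
    """(convolutional ops, reduction ops) in a derived architecture."""
    n_conv = len(spec.blocks)
    n_red = sum(1 for b in spec.blocks if b.pool != "none" and b.pool_size > 1)
    return n_conv, n_red


def alpha_trajectory_rows(state: SearchState):
    """(step, cell, candidate, weight) rows for CSV export of α curves."""
    for step, snapshot in enumerate(state.alpha_history):
        for ci, (cell, w) in enumerate(zip(state.cells, snapshot)):
            for name, wk in zip(cell.names, w):
                yield step, ci, name, float(wk)


# ---------------------------------------------------------------------------
# Planted-operation recovery experiment
# ---------------------------------------------------------------------------

def _freeze(layer: nn.Layer) -> nn.Layer:
    for lyr in layer.iter_layers():
        lyr.trainable = False
    return layer


def planted_recovery_search(seed: int, steps: int = 1500, batch_size: int = 32) -> np.ndarray:
    """Recover a planted sufficient operation with the single-level search.

    Two-class task: 100-sample signals carrying either a 5 Hz or a 15 Hz
    tone in noise.  A frozen quadrature matched-filter bank (with
    rectification) turns each signal into 4 band channels; from there, a
    depthwise-separable smoothing op — frozen at the band-envelope
    computation, the exactly-sufficient feature — competes in a mixed
    cell against a channel-collapsing candidate whose output (the mean
    envelope across all bands) carries no class information but a
    comparable scale, so the softmax(α) mixture faces a real trade-off.
    Returns the trajectory of the planted candidate's softmax(α) weight,
    one entry per update step (the last entry is the final weight).
    """
    rng = np.random.default_rng(seed)
    L, fs, k = 100, 100.0, 31
    t = np.arange(L) / fs

    def make_batch(n):
        y = rng.integers(0, 2, size=n)
        freqs = np.where(y == 0, 5.0, 15.0)
        phase = rng.uniform(0, 2 * np.pi, size=n)
        x = np.sin(2 * np.pi * freqs[:, None] * t + phase[:, None])
        x = x + 0.5 * rng.standard_normal((n, L))
        return x[:, :, None].astype(np.float32), y

    init_rng = np.random.default_rng(seed + 1)

    # shared frozen front end: quadrature matched filters for both tones
    front = nn.Conv1D(1, 4, k, init_rng)
    tt = (np.arange(k) - k // 2) / fs
    for j, (f, quad) in enumerate([(5.0, 0), (5.0, 1), (15.0, 0), (15.0, 1)]):
        front.params["W"][:, 0, j] = np.sin(2 * np.pi * f * tt) if quad == 0 else np.cos(2 * np.pi * f * tt)
    front.params["b"][:] = 0.0
    _freeze(front)

    # planted: depthwise moving-average (band envelope) + identity pointwise
    planted = _separable_branch(4, 4, 15, init_rng)
    planted.layers[0].params["W"][:] = 1.0 / 15.0
    planted.layers[0].params["b"][:] = 0.0
    planted.layers[3].params["W"][:] = np.eye(4, dtype=np.float32)[None]
    planted.layers[3].params["b"][:] = 0.0
    planted = _freeze(nn.Sequential([planted.layers[0], planted.layers[3], nn.ReLU()]))

    # uninformative competitor: same smoothing, then every output channel
    # becomes the across-band mean — class identity is erased
    collapse = _separable_branch(4, 4, 15, init_rng)
    collapse.layers[0].params["W"][:] = 1.0 / 15.0
    collapse.layers[0].params["b"][:] = 0.0
    collapse.layers[3].params["W"][:] = 0.25
    collapse.layers[3].params["b"][:] = 0.0
    dead = _freeze(nn.Sequential([collapse.layers[0], collapse.layers[3], nn.ReLU()]))

    cell = MixedCell("conv", [("planted_separable", planted), ("dead", dead)])
    head_rng = np.random.default_rng(seed + 2)
    net = nn.Sequential([front, nn.ReLU(), cell, nn.GlobalAvgPool1D(), nn.Dense(4, 2, head_rng)])
    state = SearchState(net=nn.Classifier(net, standardize=False), cells=[cell], optimizer=nn.Adam(lr=1e-3))

    from .train import one_hot

    for _ in range(steps):
        X, y = make_batch(batch_size)
        joint_update(state, X, one_hot(y, 2))
    return np.array([snap[0][0] for snap in state.alpha_history])
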