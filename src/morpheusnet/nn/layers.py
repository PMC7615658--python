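"""Minimal 1-D neural-network layers with explicit forward/backward passes.

All layers operate on float32 arrays shaped ``(batch, length, channels)``
for convolutional layers, ``(batch, features)`` for dense layers and
``(batch, time, features)`` for the LSTM.  Each layer owns its trainable
parameters in ``self.params`` and accumulates gradients of the most recent
backward pass in ``self.grads`` under the same keys.

Gradients are derived analytically per layer (no autodiff); the test suite
verifies every layer against central finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Dropout",
    "Conv1D",
    "DepthwiseConv1D",
    "BatchNorm1D",
    "MaxPool1D",
    "AvgPool1D",
    "GlobalAvgPool1D",
    "LSTM",
    "Sequential",
    "softmax",
]

_F32 = np.float32


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


class Layer:
    """Base class: trainable params, their grads, forward/backward."""

    #: parameter names that an int8 quantization plan may include
    quantizable: tuple[str, ...] = ()

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def iter_layers(self):
        """Yield every parameter-bearing leaf layer (composites override)."""
        yield self

    def n_params(self) -> int:
        return sum(int(p.size) for lyr in self.iter_layers() for p in lyr.params.values())

    def free_caches(self) -> None:
        """Drop forward-pass caches (large im2col/window buffers) everywhere."""
        for lyr in self.iter_layers():
            for name in [k for k in vars(lyr) if k.startswith("_")]:
                delattr(lyr, name)


class Dense(Layer):
    quantizable = ("W", "b")

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out, dtype=_F32)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Conv1D(Layer):
    """Standard 1-D convolution, stride 1, 'same' output length.

    Computed as k shifted matmuls over the padded input, which keeps
    memory flat and lets BLAS do the work: y[:, j] = sum_t xp[:, j+t] @ W[t].
    """

    quantizable = ("W", "b")

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left
        self.params["W"] = _glorot(rng, (kernel, c_in, c_out), kernel * c_in, kernel * c_out)
        self.params["b"] = np.zeros(c_out, dtype=_F32)

    # above this many window elements, fall back from im2col (one big GEMM,
    # needs a window copy) to the flat-memory shifted-matmul loop
    _IM2COL_MAX_ELEMS = 80_000_000

    def forward(self, x, training=False):
        W = self.params["W"]
        B, L = x.shape[0], x.shape[1]
        k = self.kernel
        if k == 1:
            self._xp, self._L, self._cols = x, L, x.reshape(B * L, self.c_in)
            return x @ W[0] + self.params["b"]
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        self._xp, self._L = xp, L
        if B * L * k * self.c_in <= self._IM2COL_MAX_ELEMS:
            win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B,L,Cin,k)
            cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * L, k * self.c_in)
            self._cols = cols
            y = (cols @ W.reshape(k * self.c_in, self.c_out)).reshape(B, L, self.c_out)
        else:
            self._cols = None
            y = np.zeros((B, L, self.c_out), dtype=x.dtype)
            for t in range(k):
                y += xp[:, t : t + L] @ W[t]
        return y + self.params["b"]

    def backward(self, dy):
        W = self.params["W"]
        xp, L = self._xp, self._L
        B = dy.shape[0]
        k, Cin = self.kernel, self.c_in
        dyf = dy.reshape(B * L, self.c_out)
        if self._cols is not None:
            self.grads["W"] = (self._cols.T @ dyf).reshape(k, Cin, self.c_out)
        else:
            dW = np.empty_like(W)
            for t in range(k):
                dW[t] = np.tensordot(xp[:, t : t + L], dy, axes=([0, 1], [0, 1]))
            self.grads["W"] = dW
        self.grads["b"] = dyf.sum(axis=0)
        if k == 1:
            return dy @ W[0].T
        dxp = np.zeros_like(xp)
        for t in range(k):
            dxp[:, t : t + L] += dy @ W[t].T
        return dxp[:, self.pad_left : self.pad_left + L]


class DepthwiseConv1D(Layer):
    """Per-channel 1-D convolution (depth multiplier 1), stride 1, 'same'."""

    quantizable = ("W", "b")

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.channels, self.kernel = channels, kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left
        self.params["W"] = _glorot(rng, (kernel, channels), kernel, kernel)
        self.params["b"] = np.zeros(channels, dtype=_F32)

    def forward(self, x, training=False):
        W = self.params["W"]
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        B, L = x.shape[0], x.shape[1]
        y = np.zeros_like(x)
        for t in range(self.kernel):
            y += xp[:, t : t + L] * W[t]
        self._xp, self._L = xp, L
        return y + self.params["b"]

    def backward(self, dy):
        W = self.params["W"]
        xp, L = self._xp, self._L
        k = self.kernel
        dW = np.empty_like(W)
        for t in range(k):
            dW[t] = (xp[:, t : t + L] * dy).sum(axis=(0, 1))
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for t in range(k):
            dxp[:, t : t + L] += dy * W[t]
        return dxp[:, self.pad_left : self.pad_left + L]


class BatchNorm1D(Layer):
    """Batch normalization over batch and length per channel.

    Works for (B, L, C) and (B, C) inputs.  Running statistics use
    exponential averaging with the given momentum.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=_F32)
        self.params["beta"] = np.zeros(channels, dtype=_F32)
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        self._axes, self._training = axes, training
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(_F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(_F32)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._xhat, self._inv = xhat, inv
            self._n = x.size // x.shape[-1]
            return self.params["gamma"] * xhat + self.params["beta"]
        # inference: one fused affine using the running statistics
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        a = self.params["gamma"] * inv
        self._inv, self._mean, self._x = inv, self.running_mean, x
        return x * a + (self.params["beta"] - self.running_mean * a)

    def backward(self, dy):
        axes = self._axes
        g = self.params["gamma"]
        if not self._training:
            xhat = (self._x - self._mean) * self._inv
            self.grads["gamma"] = (dy * xhat).sum(axis=axes)
            self.grads["beta"] = dy.sum(axis=axes)
            return dy * (g * self._inv)
        xhat, inv, n = self._xhat, self._inv, self._n
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        # dL/dx = (gamma*inv/n) * (n*dy - dbeta - xhat*dgamma), fused
        return (g * inv / n) * (n * dy - dbeta - xhat * dgamma)


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing partial window is dropped."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        B, L, C = x.shape
        n = L // self.pool
        xr = x[:, : n * self.pool].reshape(B, n, self.pool, C)
        self._arg = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy):
        B, n, C = dy.shape
        dxr = np.zeros((B, n, self.pool, C), dtype=dy.dtype)
        np.put_along_axis(dxr, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : n * self.pool] = dxr.reshape(B, n * self.pool, C)
        return dx


class AvgPool1D(Layer):
    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        B, L, C = x.shape
        n = L // self.pool
        self._in_shape = x.shape
        return x[:, : n * self.pool].reshape(B, n, self.pool, C).mean(axis=2)

    def backward(self, dy):
        B, n, C = dy.shape
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : n * self.pool] = np.repeat(dy / self.pool, self.pool, axis=1)
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x, training=False):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :] / self._L, self._L, axis=1)


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state.

    Gate order in the fused weight matrices is (input, forget, cell, output);
    the forget-gate bias is initialized to 1 as is conventional.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.units = n_in, units
        self.params["W"] = _glorot(rng, (n_in, 4 * units), n_in, units)
        self.params["U"] = _glorot(rng, (units, 4 * units), units, units)
        b = np.zeros(4 * units, dtype=_F32)
        b[units : 2 * units] = 1.0
        self.params["b"] = b

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, x, training=False):
        B, T, _ = x.shape
        H = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        self._cache = []
        self._x = x
        for t in range(T):
            z = x[:, t] @ W + h @ U + b
            i = self._sigmoid(z[:, :H])
            f = self._sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = self._sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
        return h

    def backward(self, dh_last):
        x = self._x
        B, T, _ = x.shape
        H = self.units
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh = dh_last
        dc = np.zeros((B, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dW += x[:, t].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ W.T
            dh = dz @ U.T
            dc = dc * f
        self.grads["W"], self.grads["U"], self.grads["b"] = dW, dU, db
        return dx


class Sequential(Layer):
    """Ordered chain of layers; backward runs in reverse order."""

    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=False):
        for lyr in self.layers:
            x = lyr.forward(x, training=training)
        return x

    def backward(self, dy):
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy

    def iter_layers(self):
        for lyr in self.layers:
            yield from lyr.iter_layers()
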