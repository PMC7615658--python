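"""Classifier wrapper: softmax head, cross-entropy training, checkpoints."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Sequential, softmax


def cross_entropy(probs: np.ndarray, y_onehot: np.ndarray, eps: float = 1e-12) -> float:
    return float(-(y_onehot * np.log(probs + eps)).sum() / probs.shape[0])


class Classifier:
    """A Sequential network producing logits, exposed as a softmax classifier.

    ``standardize`` applies per-sample zero-mean/unit-variance scaling over
    all non-batch axes before the first layer, which makes recordings with
    different amplitude calibrations commensurable.
    """

    def __init__(self, net: Sequential, standardize: bool = False):
        self.net = net
        self.standardize = standardize

    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if self.standardize:
            axes = tuple(range(1, x.ndim))
            mu = x.mean(axis=axes, keepdims=True)
            sd = x.std(axis=axes, keepdims=True)
            x = (x - mu) / (sd + 1e-8)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = self._prep(x)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.net.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    def train_step(self, x: np.ndarray, y_onehot: np.ndarray, optimizer) -> float:
        """One forward/backward/update on a mini-batch; returns the loss."""
        x = self._prep(x)
        logits = self.net.forward(x, training=True)
        probs = softmax(logits)
        loss = cross_entropy(probs, y_onehot)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss: {loss}")
        self.net.backward((probs - y_onehot) / len(x))
        optimizer.step(self.net)
        return loss

    # -- checkpointing ----------------------------------------------------
    def state_dict(self) -> list[dict[str, np.ndarray]]:
        state = []
        for lyr in self.net.iter_layers():
            entry = {k: v.copy() for k, v in lyr.params.items()}
            for buf in ("running_mean", "running_var"):
                if hasattr(lyr, buf):
                    entry[buf] = getattr(lyr, buf).copy()
            state.append(entry)
        return state

    def load_state_dict(self, state) -> None:
        for lyr, entry in zip(self.net.iter_layers(), state, strict=True):
            for k in lyr.params:
                lyr.params[k][...] = entry[k]
            for buf in ("running_mean", "running_var"):
                if hasattr(lyr, buf):
                    getattr(lyr, buf)[...] = entry[buf]

    def clone_state(self):
        return copy.deepcopy(self.state_dict())
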