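"""Two-stage training, evaluation metrics and the subject-wise CV harness.

Stage one trains the epoch CNN with Adam (lr 1e-3, betas 0.9/0.999,
batch 128, 10 epochs, categorical cross-entropy) and keeps the checkpoint
with the best validation accuracy.  Stage two freezes the CNN, extracts
its class-probability vectors over a trailing window of 12 epochs per
prediction, and trains the LSTM sequence learner (batch 32, lr 1e-4) the
same way.  Splits are always subject-disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix

from . import nn
from .data_io import N_CLASSES, EpochedRecording
from .model import ArchitectureSpec, BuiltModel, build_model


@dataclass
class StageConfig:
    lr: float
    batch_size: int
    epochs: int
    beta1: float = 0.9
    beta2: float = 0.999

    def __post_init__(self):
        if self.lr < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid stage configuration")


@dataclass
class TrainConfig:
    cnn: StageConfig = field(default_factory=lambda: StageConfig(lr=1e-3, batch_size=128, epochs=10))
    seq: StageConfig = field(default_factory=lambda: StageConfig(lr=1e-4, batch_size=32, epochs=10))
    seed: int = 0
    shuffle: bool = True


def one_hot(y: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    out = np.zeros((len(y), n_classes), dtype=np.float32)
    out[np.arange(len(y)), y] = 1.0
    return out


def _fit(clf: nn.Classifier, X, y, Xval, yval, cfg: StageConfig, rng: np.random.Generator):
    """Mini-batch training with best-validation-accuracy checkpointing."""
    if len(X) == 0 or len(Xval) == 0:
        raise ValueError("empty training or validation split")
    opt = nn.Adam(lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    Y = one_hot(y)
    history = {"loss": [], "val_accuracy": []}
    best_state, best_acc = clf.clone_state(), -1.0
    for _ in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses = []
        for i in range(0, len(X), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            losses.append(clf.train_step(X[idx], Y[idx], opt))
        val_acc = float((clf.predict(Xval) == yval).mean())
        history["loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_state = val_acc, clf.clone_state()
    clf.load_state_dict(best_state)
    return history


def stack_epochs(recs: list[EpochedRecording]):
    X = np.concatenate([r.epochs for r in recs])
    y = np.concatenate([r.labels for r in recs])
    return X, y


def train_cnn(model: BuiltModel, train_recs, val_recs, cfg: TrainConfig):
    """Stage one: fit the epoch CNN; returns the per-epoch history."""
    _assert_disjoint(train_recs, val_recs)
    X, y = stack_epochs(train_recs)
    Xv, yv = stack_epochs(val_recs)
    rng = np.random.default_rng(cfg.seed)
    return _fit(model.cnn, X, y, Xv, yv, cfg.cnn, rng)


def extract_probability_sequences(cnn: nn.Classifier, rec: EpochedRecording, context: int = 12):
    """Trailing windows of CNN class probabilities, one per epoch.

    The window for epoch i covers epochs [i-context+1, i]; before the
    window fits, the leading edge is padded by repeating the first
    epoch's probability vector.  Windows never cross recordings.
    """
    probs = cnn.predict_proba(rec.epochs)
    n = len(probs)
    padded = np.concatenate([np.repeat(probs[:1], context - 1, axis=0), probs])
    windows = np.stack([padded[i : i + context] for i in range(n)])
    return windows.astype(np.float32), rec.labels.copy()


def build_sequence_dataset(cnn: nn.Classifier, recs, context: int = 12):
    xs, ys = [], []
    for rec in recs:
        w, lab = extract_probability_sequences(cnn, rec, context)
        xs.append(w)
        ys.append(lab)
    return np.concatenate(xs), np.concatenate(ys)


def train_sequence(model: BuiltModel, train_recs, val_recs, cfg: TrainConfig):
    """Stage two: fit the sequence learner on frozen-CNN probability windows."""
    _assert_disjoint(train_recs, val_recs)
    ctx = model.spec.sequence.context_len
    cnn_before = _weight_checksum(model.cnn)
    X, y = build_sequence_dataset(model.cnn, train_recs, ctx)
    Xv, yv = build_sequence_dataset(model.cnn, val_recs, ctx)
    rng = np.random.default_rng(cfg.seed + 1)
    history = _fit(model.seq, X, y, Xv, yv, cfg.seq, rng)
    assert _weight_checksum(model.cnn) == cnn_before, "sequence training touched CNN weights"
    return history


def _weight_checksum(clf: nn.Classifier) -> float:
    return float(sum(np.abs(p).sum() for lyr in clf.net.iter_layers() for p in lyr.params.values()))


def predict_sequence(model: BuiltModel, rec: EpochedRecording) -> np.ndarray:
    w, _ = extract_probability_sequences(model.cnn, rec, model.spec.sequence.context_len)
    return model.seq.predict(w)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion matrix (rows = truth) and macro-averaged stage metrics in %."""

    confusion: np.ndarray
    accuracy: float
    mf1: float
    sensitivity: float
    specificity: float
    per_class: dict

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "mf1": self.mf1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_class": self.per_class,
        }


def report_from_confusion(cm: np.ndarray) -> EvalReport:
    cm = np.asarray(cm, dtype=np.int64)
    total = cm.sum()
    accuracy = 100.0 * np.trace(cm) / total if total else 0.0
    present = np.flatnonzero(cm.sum(axis=1) > 0)
    if len(present) < cm.shape[0]:
        missing = [i for i in range(cm.shape[0]) if i not in present]
        warnings.warn(f"classes {missing} absent from truth; excluded from macro averages")
    per_class = {}
    f1s, recalls, specs = [], [], []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
        per_class[k] = {"recall": recall, "precision": precision, "f1": f1, "specificity": spec}
        if k in present:
            f1s.append(f1)
            recalls.append(recall)
            specs.append(spec)
    return EvalReport(
        confusion=cm,
        accuracy=float(accuracy),
        mf1=float(np.mean(f1s)) if f1s else 0.0,
        sensitivity=float(np.mean(recalls)) if recalls else 0.0,
        specificity=float(np.mean(specs)) if specs else 0.0,
        per_class=per_class,
    )


def evaluate(predictions: np.ndarray, labels: np.ndarray) -> EvalReport:
    """Accuracy, macro F1 (MF1), macro sensitivity and macro specificity (%)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    cm = confusion_matrix(labels, predictions, labels=list(range(N_CLASSES)))
    return report_from_confusion(cm)


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Subject-wise fold assignments; 'loo' is k-fold with k = n subjects."""

    k: int
    folds: list[list[str]]  # subject ids per test fold

    @classmethod
    def kfold(cls, subject_ids: list[str], k: int, seed: int = 0) -> "SplitPlan":
        if k > len(subject_ids):
            raise ValueError(f"k={k} exceeds the {len(subject_ids)} available subjects")
        order = list(np.array(subject_ids)[np.random.default_rng(seed).permutation(len(subject_ids))])
        folds = [order[i::k] for i in range(k)]
        return cls(k=k, folds=folds)

    @classmethod
    def loo(cls, subject_ids: list[str]) -> "SplitPlan":
        return cls(k=len(subject_ids), folds=[[s] for s in subject_ids])


def _assert_disjoint(*groups):
    seen: set[str] = set()
    for recs in groups:
        ids = {r.subject_id for r in recs}
        if ids & seen:
            raise ValueError(f"subject leakage across splits: {ids & seen}")
        seen |= ids


def train_two_stage(spec: ArchitectureSpec, train_recs, val_recs, cfg: TrainConfig) -> BuiltModel:
    model = build_model(spec, seed=cfg.seed)
    train_cnn(model, train_recs, val_recs, cfg)
    train_sequence(model, train_recs, val_recs, cfg)
    return model


def run_cross_validation(dataset: list[EpochedRecording], plan: SplitPlan, spec: ArchitectureSpec, cfg: TrainConfig, val_fraction: float = 0.1):
    """Full two-stage training per fold; pooled report from summed confusions."""
    by_id = {r.subject_id: r for r in dataset}
    fold_reports = []
    pooled_cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for fold_idx, test_ids in enumerate(plan.folds):
        rest = [s for s in by_id if s not in test_ids]
        rng = np.random.default_rng(cfg.seed + fold_idx)
        rest = list(np.array(rest)[rng.permutation(len(rest))])
        n_val = max(1, int(round(val_fraction * len(rest))))
        val_ids, train_ids = rest[:n_val], rest[n_val:]
        if not train_ids:
            raise ValueError("fold leaves no training subjects")
        model = train_two_stage(
            spec, [by_id[s] for s in train_ids], [by_id[s] for s in val_ids], cfg
        )
        preds = np.concatenate([predict_sequence(model, by_id[s]) for s in test_ids])
        labels = np.concatenate([by_id[s].labels for s in test_ids])
        rep = evaluate(preds, labels)
        fold_reports.append(rep)
        pooled_cm += rep.confusion
    return fold_reports, report_from_confusion(pooled_cm)
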