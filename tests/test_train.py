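"""Metrics, probability-window extraction, split hygiene and training loops."""

import numpy as np
import pytest

from morpheusnet import synthetic
from morpheusnet.data_io import EpochedRecording
from morpheusnet.model import default_spec, build_model
from morpheusnet.train import (
    SplitPlan,
    StageConfig,
    TrainConfig,
    evaluate,
    extract_probability_sequences,
    report_from_confusion,
    run_cross_validation,
    stack_epochs,
    train_cnn,
)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def brute_force_metrics(pred, truth, n_classes=5):
    """Independent pure-python confusion-matrix metrics (macro averages)."""
    cm = [[0] * n_classes for _ in range(n_classes)]
    for t, p in zip(truth, pred):
        cm[t][p] += 1
    total = len(truth)
    acc = 100.0 * sum(cm[k][k] for k in range(n_classes)) / total
    f1s, recalls, specs = [], [], []
    for k in range(n_classes):
        tp = cm[k][k]
        fn = sum(cm[k]) - tp
        fp = sum(cm[r][k] for r in range(n_classes)) - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            continue  # class absent from truth
        rec = 100.0 * tp / (tp + fn)
        prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        recalls.append(rec)
        specs.append(100.0 * tn / (tn + fp) if tn + fp else 0.0)
    mean = lambda v: sum(v) / len(v) if v else 0.0
    return cm, acc, mean(f1s), mean(recalls), mean(specs)


class TestEvaluate:
    def test_perfect_predictions_score_100(self):
        y = np.array([0, 1, 2, 3, 4] * 3)
        rep = evaluate(y, y)
        assert (rep.accuracy, rep.mf1, rep.sensitivity, rep.specificity) == (100, 100, 100, 100)

    def test_hand_computed_two_class_example(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 1, 1, 1])
        with pytest.warns(UserWarning, match="absent"):
            rep = evaluate(pred, truth)
        assert rep.accuracy == pytest.approx(75.0)
        assert rep.mf1 == pytest.approx((200 / 3 + 80) / 2, abs=0.01)  # 73.33
        assert rep.sensitivity == pytest.approx(75.0)
        assert rep.specificity == pytest.approx(75.0)

    def test_constant_predictor_on_balanced_truth(self):
        truth = np.array([0, 1, 2, 3, 4] * 10)
        pred = np.zeros(50, dtype=int)
        rep = evaluate(pred, truth)
        assert rep.accuracy == pytest.approx(20.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0, 1]), np.array([0]))

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            truth = rng.integers(0, 5, n)
            pred = rng.integers(0, 5, n)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = evaluate(pred, truth)
            cm, acc, mf1, sens, spec = brute_force_metrics(pred.tolist(), truth.tolist())
            assert rep.confusion.tolist() == cm
            assert rep.accuracy == pytest.approx(acc, abs=1e-9)
            assert rep.mf1 == pytest.approx(mf1, abs=1e-9)
            assert rep.sensitivity == pytest.approx(sens, abs=1e-9)
            assert rep.specificity == pytest.approx(spec, abs=1e-9)


# ---------------------------------------------------------------------------
# Probability windows
# ---------------------------------------------------------------------------

class _ConstantCNN:
    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=np.float32)

    def predict_proba(self, x, batch_size=256):
        return np.tile(self.probs, (len(x), 1))


class TestSequenceExtraction:
    def _rec(self, n):
        return EpochedRecording(np.zeros((n, 3000, 1)), np.zeros(n, dtype=int))

    def test_one_window_per_epoch_with_leading_padding(self):
        cnn = _ConstantCNN([0.2] * 5)
        windows, labels = extract_probability_sequences(cnn, self._rec(12), context=12)
        assert windows.shape == (12, 12, 5)
        assert len(labels) == 12

    def test_constant_cnn_yields_identical_windows(self):
        cnn = _ConstantCNN([0.1, 0.2, 0.3, 0.2, 0.2])
        windows, _ = extract_probability_sequences(cnn, self._rec(20), context=12)
        assert np.allclose(windows, windows[0])

    def test_padding_repeats_first_epoch_probabilities(self):
        class RampCNN:
            def predict_proba(self, x, batch_size=256):
                n = len(x)
                out = np.zeros((n, 5), dtype=np.float32)
                out[:, 0] = np.arange(n)
                return out

        windows, _ = extract_probability_sequences(RampCNN(), self._rec(15), context=12)
        assert (windows[0, :, 0] == 0).all()  # fully padded first window
        assert windows[5, 0, 0] == 0  # still padded at the leading edge
        assert windows[14, -1, 0] == 14


# ---------------------------------------------------------------------------
# Splits and CV bookkeeping
# ---------------------------------------------------------------------------

class TestSplits:
    def test_kfold_is_subject_disjoint_and_exhaustive(self):
        ids = [f"S{i}" for i in range(10)]
        plan = SplitPlan.kfold(ids, 5, seed=3)
        seen = [s for fold in plan.folds for s in fold]
        assert sorted(seen) == sorted(ids)

    def test_loo_on_five_subjects_tests_each_once(self):
        plan = SplitPlan.loo([f"S{i}" for i in range(5)])
        assert plan.k == 5
        assert all(len(f) == 1 for f in plan.folds)

    def test_k_larger_than_subject_pool_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan.kfold(["a", "b"], 3)

    def test_fold_assignment_deterministic_given_seed(self):
        ids = [f"S{i}" for i in range(8)]
        assert SplitPlan.kfold(ids, 4, seed=9).folds == SplitPlan.kfold(ids, 4, seed=9).folds

    def test_leakage_detection(self, small_dataset):
        cfg = TrainConfig(seed=0)
        model = build_model(default_spec(), seed=0)
        with pytest.raises(ValueError, match="leakage"):
            train_cnn(model, small_dataset, small_dataset[:1], cfg)


# ---------------------------------------------------------------------------
# Training loops (small overfit smokes; the full pipeline has its own tests)
# ---------------------------------------------------------------------------

def _toy_recordings(rng, n_epochs=24):
    """Linearly separable two-class toy: W epochs vs N3 epochs."""
    models = synthetic.default_stage_models()
    recs = []
    for sid in range(3):
        labels = np.array([0, 3] * (n_epochs // 2))
        epochs = np.stack(
            [synthetic.generate_epoch(l, models, int(rng.integers(2**31))) for l in labels]
        )
        recs.append(EpochedRecording(epochs, labels, subject_id=f"T{sid}"))
    return recs


class TestTrainingLoops:
    @pytest.fixture(scope="class")
    def toy_history(self):
        rng = np.random.default_rng(0)
        recs = _toy_recordings(rng)
        cfg = TrainConfig(cnn=StageConfig(lr=1e-3, batch_size=16, epochs=6), seed=0)
        model = build_model(default_spec(), seed=0)
        hist = train_cnn(model, recs[:2], recs[2:], cfg)
        return model, recs, hist

    def test_two_class_toy_reaches_high_train_accuracy(self, toy_history):
        model, recs, _ = toy_history
        X, y = stack_epochs(recs[:2])
        assert (model.cnn.predict(X) == y).mean() >= 0.99

    def test_checkpoint_matches_best_validation_accuracy(self, toy_history):
        model, recs, hist = toy_history
        Xv, yv = stack_epochs(recs[2:])
        assert (model.cnn.predict(Xv) == yv).mean() == pytest.approx(
            max(hist["val_accuracy"]), abs=1e-9
        )

    def test_fixed_seed_reproduces_history(self):
        rng = np.random.default_rng(1)
        recs = _toy_recordings(rng, n_epochs=8)
        cfg = TrainConfig(cnn=StageConfig(lr=1e-3, batch_size=8, epochs=2), seed=5)
        h1 = train_cnn(build_model(default_spec(), seed=5), recs[:2], recs[2:], cfg)
        h2 = train_cnn(build_model(default_spec(), seed=5), recs[:2], recs[2:], cfg)
        assert h1 == h2


class TestCrossValidation:
    def test_pooled_confusion_is_sum_of_folds(self):
        recs = _toy_recordings(np.random.default_rng(2), n_epochs=8)
        recs += _toy_recordings(np.random.default_rng(3), n_epochs=8)
        for i, r in enumerate(recs):
            r.subject_id = f"S{i}"
        cfg = TrainConfig(
            cnn=StageConfig(lr=1e-3, batch_size=8, epochs=1),
            seq=StageConfig(lr=1e-3, batch_size=8, epochs=1),
            seed=0,
        )
        plan = SplitPlan.kfold([r.subject_id for r in recs], 3, seed=0)
        folds, pooled = run_cross_validation(recs, plan, default_spec(), cfg)
        assert np.array_equal(pooled.confusion, sum(f.confusion for f in folds))
        assert pooled.confusion.sum() == sum(r.n_epochs for r in recs)


def test_report_from_confusion_accuracy_identity(rng):
    cm = rng.integers(0, 30, (5, 5))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = report_from_confusion(cm)
    assert rep.accuracy == pytest.approx(100 * np.trace(cm) / cm.sum())
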