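"""Training engine and cross-validation drivers: gradient correctness,
stopping rules, determinism, and bookkeeping conservation."""

import numpy as np
import pytest

from minet.network import ModelConfig
from minet.nn import NNetClassifier
from minet.training import GridResult, TrainConfig, grid_search, repeated_cv, train_model


def toy_data(n=40, n_classes=2, seed=0, length=60):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, 12, length)).astype(np.float32)
    y = rng.integers(0, n_classes, n)
    for c in range(n_classes):
        X[y == c, :, 10 + 5 * c : 15 + 5 * c] += 3.0
    return X, y


class TestGradients:
    def test_backward_matches_directional_derivative(self):
        """Analytic gradient agrees with a central finite difference along a
        random direction through every parameter."""
        config = ModelConfig(2, 2, 3, input_length=24)
        model = NNetClassifier(config, seed=3)
        for path in model.paths:  # float64 so finite differences are clean
            for layer in path:
                layer.W = layer.W.astype(np.float64)
                layer.b = layer.b.astype(np.float64)
        model.head_W = model.head_W.astype(np.float64)
        model.head_b = model.head_b.astype(np.float64)
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (5, 12, 24))
        y = np.array([0, 1, 2, 1, 0])
        onehot = np.eye(3, dtype=np.float32)[y]
        probs, cache = model._forward(X, train=False)
        grads = model._backward(probs, onehot, cache)
        flat = []
        for path in grads["conv"]:
            for dW, db in path:
                flat.extend([dW, db])
        flat.extend([grads["head_W"], grads["head_b"]])
        params = model.parameters()

        def loss():
            p, _ = model._forward(X, train=False)
            return float(-np.mean(np.log(np.clip(p[np.arange(5), y], 1e-12, None))))

        dir_rng = np.random.default_rng(7)
        direction = [dir_rng.normal(0, 1, p.shape) for p in params]
        eps = 1e-4
        base = [p.copy() for p in params]
        for p, b, d in zip(params, base, direction):
            p[...] = b + eps * d
        lp = loss()
        for p, b, d in zip(params, base, direction):
            p[...] = b - eps * d
        lm = loss()
        for p, b in zip(params, base):
            p[...] = b
        numeric = (lp - lm) / (2 * eps)
        analytic = sum(float(np.sum(g * d)) for g, d in zip(flat, direction))
        assert analytic == pytest.approx(numeric, rel=0.02)


class TestStoppingRules:
    def test_frozen_monitor_stops_after_patience(self):
        """With learning rate zero the loss never improves after epoch 1, so
        training halts after exactly patience further epochs."""
        X, y = toy_data()
        # dropout off so the monitored loss is exactly constant at zero lr
        config = ModelConfig(1, 2, 2, input_length=60, dropout_rate=0.0)
        model = NNetClassifier(config, seed=0)
        history = model.fit(X, y, learning_rate=0.0, batch_size=40,
                            max_epochs=50, patience=5)
        assert len(history["train_loss"]) == 6

    def test_max_epoch_cap(self):
        X, y = toy_data()
        model = NNetClassifier(ModelConfig(1, 2, 2, input_length=60), seed=0)
        history = model.fit(X, y, batch_size=10, max_epochs=8, patience=7)
        assert len(history["train_loss"]) <= 8

    def test_patience_must_be_smaller_than_max_epochs(self):
        with pytest.raises(ValueError, match="patience"):
            TrainConfig(max_epochs=20, patience=20)

    def test_empty_training_set_rejected(self):
        model = NNetClassifier(ModelConfig(1, 2, 2, input_length=60), seed=0)
        with pytest.raises(ValueError, match="empty"):
            model.fit(np.zeros((0, 12, 60), dtype=np.float32), np.zeros(0, dtype=int))

    def test_label_class_mismatch_rejected(self):
        X, _ = toy_data(10)
        model = NNetClassifier(ModelConfig(1, 2, 2, input_length=60), seed=0)
        with pytest.raises(ValueError, match="label"):
            model.fit(X, np.full(10, 5))

    def test_best_epoch_weights_restored(self):
        X, y = toy_data()
        model = NNetClassifier(ModelConfig(1, 2, 2, input_length=60), seed=0)
        history = model.fit(X, y, batch_size=10, max_epochs=12, patience=11)
        best = int(np.argmin(history["train_loss"]))
        assert history["train_loss"][best] == min(history["train_loss"])


class TestDeterminism:
    def test_identical_seeds_reproduce_training(self):
        X, y = toy_data()
        tc = TrainConfig(batch_size=20, max_epochs=6, patience=5)
        config = ModelConfig(1, 3, 2, input_length=60)
        m1, h1 = train_model(config, X, y, tc, seed=4)
        m2, h2 = train_model(config, X, y, tc, seed=4)
        assert h1["train_loss"] == h2["train_loss"]
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_different_init_seeds_differ(self):
        X, y = toy_data()
        tc = TrainConfig(batch_size=20, max_epochs=4, patience=3)
        config = ModelConfig(1, 3, 2, input_length=60)
        _, h1 = train_model(config, X, y, tc, seed=4)
        _, h2 = train_model(config, X, y, tc, seed=5)
        assert h1["train_loss"] != h2["train_loss"]


@pytest.fixture(scope="module")
def quick_cv(tiny_bundles):
    """One cheap repeated CV on the tiny detection bundle (contract checks)."""
    _, detection, _ = tiny_bundles
    tc = TrainConfig(batch_size=60, max_epochs=4, patience=3)
    result = repeated_cv(ModelConfig(1, 2, 2), detection, k=3, repeats=2,
                         base_seed=1, train_config=tc)
    return detection, result


class TestRepeatedCv:
    def test_confusion_conservation(self, quick_cv):
        detection, result = quick_cv
        X, y, _ = detection.to_arrays()
        true_counts = np.bincount(y, minlength=2)
        for cm in result.confusions:
            assert cm.sum() == detection.n_pieces
            np.testing.assert_array_equal(cm.sum(axis=1), true_counts)

    def test_metrics_reported_per_repeat(self, quick_cv):
        _, result = quick_cv
        per = result.per_repeat_indexes()
        assert set(per) == {"ACC", "SEN", "SPE", "F1", "AUC"}
        assert all(v.shape == (2,) for v in per.values())
        assert result.accuracies.shape == (2,)

    def test_cv_reproducible(self, tiny_bundles):
        _, detection, _ = tiny_bundles
        tc = TrainConfig(batch_size=60, max_epochs=3, patience=2)
        a = repeated_cv(ModelConfig(1, 2, 2), detection, k=3, repeats=1,
                        base_seed=9, train_config=tc)
        b = repeated_cv(ModelConfig(1, 2, 2), detection, k=3, repeats=1,
                        base_seed=9, train_config=tc)
        np.testing.assert_array_equal(a.confusions, b.confusions)

    def test_class_count_mismatch_rejected(self, tiny_bundles):
        _, detection, _ = tiny_bundles
        with pytest.raises(ValueError, match="classes"):
            repeated_cv(ModelConfig(1, 2, 6), detection, k=3, repeats=1)


class TestGridSearch:
    def test_subgrid_entries_and_best(self, tiny_bundles):
        _, detection, _ = tiny_bundles
        tc = TrainConfig(batch_size=60, max_epochs=3, patience=2)
        configs = [ModelConfig(1, f, 2) for f in (1, 2)]
        result = grid_search("detection", detection, k=3, repeats=1, base_seed=2,
                             train_config=tc, configs=configs)
        assert set(result.entries) == {(1, 1), (1, 2)}
        best = result.best
        assert result.entries[best]["mean_acc"] == max(
            e["mean_acc"] for e in result.entries.values()
        )

    def test_tie_broken_toward_fewer_parameters(self):
        entries = {
            (1, 2): {"mean_acc": 90.0, "sd_acc": 1.0, "n_parameters": 500},
            (2, 1): {"mean_acc": 90.0, "sd_acc": 1.0, "n_parameters": 400},
            (1, 1): {"mean_acc": 80.0, "sd_acc": 1.0, "n_parameters": 122},
        }
        result = GridResult(task="detection", entries=entries, results={})
        assert result.best == (2, 1)

    def test_task_mismatch_rejected(self, tiny_bundles):
        locating, _, _ = tiny_bundles
        with pytest.raises(ValueError, match="task"):
            grid_search("detection", locating, repeats=1)
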