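"""Feed-forward lesion classifier: architecture, loss, protocol building blocks."""

import numpy as np
import pytest

from ceustic.classifier import (
    FeedForwardClassifier,
    NetworkSpec,
    TrainConfig,
    count_parameters,
    dataset_from_frame,
    focal_cross_entropy,
    load_model,
    oversample,
    predict,
    probability_report,
    save_model,
    split_dataset,
    train_classifier,
)
from ceustic.synthetic import LABEL_COLUMNS, generate_patient_table


class TestParameterCount:
    def test_default_network_has_203_parameters(self):
        assert count_parameters(NetworkSpec()) == 203

    def test_layerwise_arithmetic(self):
        # 8*8+8, 8*6+6, 6*6+6, 6*5+5
        assert [72, 54, 42, 35] == [
            count_parameters(NetworkSpec(n, (w,))) for n, w in [(8, 8), (8, 6), (6, 6), (6, 5)]
        ]

    def test_single_unit_layer(self):
        assert count_parameters(NetworkSpec(1, (1,))) == 2

    def test_constructed_network_matches_by_walking_layers(self):
        net = FeedForwardClassifier(NetworkSpec(), seed=0)
        assert net.n_parameters() == 203


class TestFocalLoss:
    ONE_HOT = np.array([0.0, 1.0, 0.0, 0.0, 0.0])

    def probs(self, p_true):
        rest = (1.0 - p_true) / 4.0
        p = np.full(5, rest)
        p[1] = p_true
        return p

    def test_perfect_prediction_zero_loss(self):
        assert focal_cross_entropy(self.probs(1.0), self.ONE_HOT) == pytest.approx(0.0, abs=1e-5)

    def test_reduces_to_cross_entropy(self):
        p = self.probs(0.3)
        ce = focal_cross_entropy(p, self.ONE_HOT, alpha=1.0, gamma=0.0)
        assert ce == pytest.approx(-np.log(0.3), rel=1e-12)

    def test_hand_computed_value(self):
        # 0.25 * (1 - 0.2)^2 * (-ln 0.2)
        loss = focal_cross_entropy(self.probs(0.2), self.ONE_HOT, alpha=0.25, gamma=2.0)
        assert loss == pytest.approx(0.25 * 0.64 * -np.log(0.2), abs=1e-6)

    def test_monotone_decreasing_in_p_true(self):
        losses = [focal_cross_entropy(self.probs(p), self.ONE_HOT) for p in (0.1, 0.4, 0.7, 0.95)]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert all(l >= 0 for l in losses)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            focal_cross_entropy(np.array([0.5, 0.6]), np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            focal_cross_entropy(np.array([0.5, 0.5]), np.array([1.0, 1.0]))

    def test_gradient_matches_finite_differences(self):
        """Backprop through softmax + focal loss agrees with numeric gradients."""
        rng = np.random.default_rng(0)
        net = FeedForwardClassifier(NetworkSpec(), seed=3)
        X = rng.normal(size=(12, 8))
        onehot = np.zeros((12, 5))
        onehot[np.arange(12), rng.integers(0, 5, 12)] = 1.0

        probs = net.forward(X)
        net.backward_from_focal(probs, onehot, alpha=0.25, gamma=2.0)
        grads = [g.copy() for g in net.grads]

        def loss():
            return focal_cross_entropy(net.forward(X), onehot, 0.25, 2.0)

        rng2 = np.random.default_rng(1)
        for p, g in zip(net.params, grads):
            flat, gf = p.reshape(-1), g.reshape(-1)
            for idx in rng2.choice(flat.size, size=min(4, flat.size), replace=False):
                eps, orig = 1e-6, flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(gf[idx], rel=1e-4, abs=1e-9)


class TestOversample:
    def test_balances_to_majority_count(self):
        y = np.repeat([0, 1, 2, 3, 4], [24, 10, 10, 10, 5])
        X = np.arange(len(y), dtype=float)[:, None]
        Xo, yo = oversample(X, y, seed=0)
        _, counts = np.unique(yo, return_counts=True)
        assert counts.tolist() == [24] * 5

    def test_already_balanced_unchanged(self):
        y = np.repeat([0, 1, 2, 3, 4], 6)
        X = np.arange(len(y), dtype=float)[:, None]
        Xo, yo = oversample(X, y, seed=0)
        assert np.array_equal(Xo, X) and np.array_equal(yo, y)

    def test_duplicates_are_exact_copies_and_originals_kept(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], [20, 5])
        X = rng.normal(size=(25, 8))
        Xo, yo = oversample(X, y, seed=1)
        assert np.array_equal(Xo[:25], X)
        originals = {row.tobytes() for row in X}
        assert all(row.tobytes() in originals for row in Xo)


class TestSplit:
    def test_balanced_100_gives_14_6_per_class(self):
        y = np.repeat(np.arange(5), 20)
        X = np.arange(100, dtype=float)[:, None]
        X_tr, y_tr, X_va, y_va = split_dataset(X, y, 0.70, seed=0)
        assert [int((y_tr == c).sum()) for c in range(5)] == [14] * 5
        assert [int((y_va == c).sum()) for c in range(5)] == [6] * 5
        assert not set(X_tr[:, 0]) & set(X_va[:, 0])

    def test_deterministic(self):
        y = np.repeat(np.arange(5), 10)
        X = np.arange(50, dtype=float)[:, None]
        a = split_dataset(X, y, seed=7)
        b = split_dataset(X, y, seed=7)
        for u, v in zip(a, b):
            assert np.array_equal(u, v)

    def test_singleton_class_rejected(self):
        y = np.array([0, 0, 1])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_dataset(np.zeros((3, 8)), y)

    def test_no_validation_row_in_oversampled_training(self):
        """Split-before-oversample: no leakage when raw rows are unique."""
        df = generate_patient_table(200, seed=5)
        X, y = dataset_from_frame(df)
        X_tr, y_tr, X_va, _ = split_dataset(X, y, 0.70, seed=0)
        Xo, _ = oversample(X_tr, y_tr, seed=0)
        val_rows = {row.tobytes() for row in X_va}
        assert not any(row.tobytes() in val_rows for row in Xo)


class TestTraining:
    def test_same_seed_identical_history(self):
        X, y = dataset_from_frame(generate_patient_table(200, separation=3.0, seed=1))
        cfg = TrainConfig(seed=2, epochs=10)
        a = train_classifier(X, y, config=cfg)
        b = train_classifier(X, y, config=cfg)
        assert a.history == b.history

    def test_loss_decreases_on_separable_data(self):
        X, y = dataset_from_frame(generate_patient_table(400, separation=5.0, seed=3))
        model = train_classifier(X, y, config=TrainConfig(seed=0, epochs=30))
        h = model.history["train_loss"]
        assert h[-1] < h[0]

    def test_nonfinite_features_rejected(self):
        X = np.full((20, 8), np.nan)
        y = np.repeat(np.arange(5), 4)
        with pytest.raises(ValueError, match="finite"):
            train_classifier(X, y)

    def test_predict_contract(self):
        X, y = dataset_from_frame(generate_patient_table(150, separation=3.0, seed=4))
        model = train_classifier(X, y, config=TrainConfig(seed=1, epochs=5))
        probs = predict(model, X[0])
        assert probs.shape == (5,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(probs >= 0)
        report = probability_report(probs)
        assert list(report) == list(LABEL_COLUMNS)

    def test_untrained_predict_rejected(self):
        from ceustic.classifier import TrainedModel

        model = TrainedModel(FeedForwardClassifier(), np.zeros(8), np.ones(8), TrainConfig())
        with pytest.raises(RuntimeError, match="trained"):
            predict(model, np.zeros(8))

    def test_checkpoint_roundtrip(self, tmp_path):
        X, y = dataset_from_frame(generate_patient_table(150, separation=3.0, seed=4))
        model = train_classifier(X, y, config=TrainConfig(seed=1, epochs=5))
        save_model(model, tmp_path / "model.npz")
        back = load_model(tmp_path / "model.npz")
        np.testing.assert_allclose(back.predict_proba(X[:10]), model.predict_proba(X[:10]))
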