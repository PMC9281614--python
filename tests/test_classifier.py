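"""Bi-LSTM classifier: gradients, training behavior, folds."""

import numpy as np
import pytest

import ecgsqa as e
from ecgsqa.classifier import (
    ClassifierConfig,
    _LSTMDirection,
    kfold_indices,
    predict,
    train,
)
from ecgsqa.synth import Label


def _separable_features(n_per_class=20, p=12, t=8, shift=5.0, seed=0):
    """Three Gaussian clouds whose means differ by `shift` standard deviations."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k, lab in enumerate((Label.A, Label.B, Label.C)):
        mean = np.zeros((p, t))
        mean[k % p, :] = shift
        X.append(mean + rng.standard_normal((n_per_class, p, t)))
        y += [lab] * n_per_class
    return np.concatenate(X), y


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        """Analytic LSTM gradients agree with central differences on a tiny net."""
        rng = np.random.default_rng(0)
        cell = _LSTMDirection(d_in=3, hidden=4, rng=rng)
        x = rng.standard_normal((2, 5, 3))
        w_out = rng.standard_normal(4)  # loss = sum over batch of h_final . w_out

        cell.forward(x)
        grads = cell.backward(np.tile(w_out, (2, 1)))
        eps = 1e-6
        for p_idx, p in enumerate(cell.params()):
            for _ in range(5):  # spot-check a few coordinates
                idx = tuple(int(rng.integers(0, s)) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                up = (cell.forward(x) @ w_out).sum()
                p[idx] = orig - eps
                dn = (cell.forward(x) @ w_out).sum()
                p[idx] = orig
                num = (up - dn) / (2 * eps)
                assert grads[p_idx][idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestTrain:
    def test_default_config_mirrors_study_settings(self):
        cfg = ClassifierConfig()
        assert cfg.max_epochs == 1000
        assert cfg.batch_size == 490
        assert cfg.bidirectional

    def test_single_class_needs_override(self):
        X, _ = _separable_features(4)
        with pytest.raises(ValueError):
            train(X[:4], [Label.A] * 4, ClassifierConfig.desk(max_epochs=1))
        model = train(
            X[:4], [Label.A] * 4,
            ClassifierConfig.desk(max_epochs=1, allow_single_class=True),
        )
        labs = e.predict_labels(model, X[4:8])
        assert labs == [Label.A] * 4

    def test_separable_data_learned_within_30_epochs(self):
        X, y = _separable_features()
        cfg = ClassifierConfig.desk(
            max_epochs=30, hidden_units=16, batch_size=16, seed=1
        )
        model = train(X, y, cfg)
        acc = np.mean([p == t for p, t in zip(e.predict_labels(model, X), y)])
        assert acc >= 0.99
        assert model.training_log[-1] <= model.training_log[0]

    def test_training_deterministic_given_seed(self):
        X, y = _separable_features(8)
        cfg = ClassifierConfig.desk(max_epochs=5, hidden_units=8, batch_size=8, seed=3)
        m1, m2 = train(X, y, cfg), train(X, y, cfg)
        np.testing.assert_array_equal(m1.Wo, m2.Wo)
        assert m1.training_log == m2.training_log

    def test_length_mismatch_rejected(self):
        X, y = _separable_features(4)
        with pytest.raises(ValueError):
            train(X, y[:-1], ClassifierConfig.desk(max_epochs=1))


class TestPredict:
    def test_probability_simplex(self):
        X, y = _separable_features(6)
        model = train(X, y, ClassifierConfig.desk(max_epochs=3, hidden_units=8,
                                                  batch_size=8, seed=0))
        for _, p in predict(model, X):
            assert (p >= 0).all()
            assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_batch_order_invariance(self):
        X, y = _separable_features(6)
        model = train(X, y, ClassifierConfig.desk(max_epochs=3, hidden_units=8,
                                                  batch_size=8, seed=0))
        base = predict(model, X)
        perm = np.random.default_rng(0).permutation(len(X))
        shuffled = predict(model, X[perm])
        for k, orig_idx in enumerate(perm):
            assert shuffled[k][0] == base[orig_idx][0]
            np.testing.assert_allclose(shuffled[k][1], base[orig_idx][1], atol=1e-12)

    def test_feature_shape_mismatch_rejected(self):
        X, y = _separable_features(4)
        model = train(X, y, ClassifierConfig.desk(max_epochs=1, hidden_units=4,
                                                  batch_size=8, seed=0))
        with pytest.raises(ValueError):
            predict(model, X[:, :, :-1])


class TestCheckpoint:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path):
        X, y = _separable_features(6)
        cfg = ClassifierConfig.desk(max_epochs=5, hidden_units=8, batch_size=8,
                                    seed=4, standardize=True)
        model = train(X, y, cfg)
        e.save_model(model, tmp_path / "model.npz")
        back = e.load_model(tmp_path / "model.npz")
        base = predict(model, X)
        again = predict(back, X)
        assert [a[0] for a in base] == [b[0] for b in again]
        np.testing.assert_allclose(
            np.stack([p for _, p in base]), np.stack([p for _, p in again])
        )
        assert back.training_log == model.training_log


class TestFolds:
    def test_exact_fold_sizes(self):
        folds = kfold_indices(100, 10, seed=0)
        assert all(f.size == 10 for f in folds)

    @pytest.mark.parametrize("n", range(4, 31))
    def test_partition_property_exhaustive(self, n):
        for k in range(2, min(n, 8) + 1):
            folds = kfold_indices(n, k, seed=n * 100 + k)
            allv = np.concatenate(folds)
            assert allv.size == n
            assert np.array_equal(np.sort(allv), np.arange(n))

    def test_stratified_folds_preserve_class_balance(self):
        labels = [Label.A] * 30 + [Label.B] * 30 + [Label.C] * 30
        folds = kfold_indices(90, 3, seed=1, labels=labels, stratified=True)
        for f in folds:
            counts = {lab: sum(1 for i in f if labels[i] is lab) for lab in Label}
            assert counts == {Label.A: 10, Label.B: 10, Label.C: 10}
        allv = np.sort(np.concatenate(folds))
        assert np.array_equal(allv, np.arange(90))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(5, 6, seed=0)

    def test_crossvalidate_reproducible_and_above_chance(self):
        X, y = _separable_features(12, seed=5)
        cfg = ClassifierConfig.desk(max_epochs=15, hidden_units=8, batch_size=12,
                                    seed=2)
        folds1, mean1 = e.crossvalidate(X, y, k=3, config=cfg, seed=7)
        folds2, mean2 = e.crossvalidate(X, y, k=3, config=cfg, seed=7)
        assert mean1.macc == mean2.macc
        assert [r.macc for r in folds1] == [r.macc for r in folds2]
        assert mean1.macc > 33.4 * 2  # far above the 1/3 chance level
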