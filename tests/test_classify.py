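"""Classifier contracts: architecture output, gradient correctness, the
split/cross-validation protocol, evaluation arithmetic and serialization."""

import numpy as np
import pytest

from sherpa_eeg import (
    EpochClassifier,
    ModelSpec,
    TrainingConfig,
    evaluate,
    simulate_epochs,
    split_data,
    train_crossval,
)
from sherpa_eeg._network import Adam, ConvNet

from conftest import make_epochs, tiny_simulation

TINY = dict(conv_filters=(4, 8), kernel_size=9, pool_size=2, dense_units=(16,))


class TestConvNet:
    def test_softmax_rows_and_output_width(self, rng):
        net = ConvNet(6, 64, 3, **TINY, seed=0)
        x = rng.normal(size=(5, 6, 64)).astype(np.float32)
        p = net.predict_proba(x)
        assert p.shape == (5, 3)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_build_determinism(self, rng):
        x = rng.normal(size=(4, 6, 64)).astype(np.float32)
        a = ConvNet(6, 64, 3, **TINY, seed=42).predict_proba(x)
        b = ConvNet(6, 64, 3, **TINY, seed=42).predict_proba(x)
        np.testing.assert_array_equal(a, b)

    def test_kernel_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            ConvNet(6, 8, 3, conv_filters=(4,), kernel_size=9)

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(77)  # fixed probes: float32 FD is noisy
        net = ConvNet(3, 20, 3, conv_filters=(4, 6), kernel_size=5,
                      pool_size=2, dense_units=(8,), l2=0.0, seed=1)
        x = rng.normal(size=(3, 3, 20)).astype(np.float32)
        y = np.eye(3, dtype=np.float32)[rng.integers(0, 3, 3)]
        for _ in range(3):  # prime BatchNorm running stats
            net.loss_and_param_grads(x, y)
        g = net.output_input_gradient(x, 1)
        eps = 1e-3
        for _ in range(20):
            t = rng.integers(0, 3)
            c = rng.integers(0, 3)
            s = rng.integers(0, 20)
            xp, xm = x.copy(), x.copy()
            xp[t, c, s] += eps
            xm[t, c, s] -= eps
            num = (net.predict_proba(xp)[t, 1] - net.predict_proba(xm)[t, 1]) / (2 * eps)
            assert abs(num - g[t, c, s]) < 1e-3

    def test_param_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(99)  # fixed probes: float32 FD is noisy
        net = ConvNet(3, 20, 3, conv_filters=(4, 6), kernel_size=5,
                      pool_size=2, dense_units=(8,), l2=0.0, seed=1)
        x = rng.normal(size=(4, 3, 20)).astype(np.float32)
        y = np.eye(3, dtype=np.float32)[rng.integers(0, 3, 4)]
        net.loss_and_param_grads(x, y)
        layer = net.layers[1]  # first conv
        gW = layer.grads["W"].copy()
        eps = 1e-3
        for _ in range(8):
            i = tuple(rng.integers(0, s) for s in layer.params["W"].shape)
            w0 = layer.params["W"][i]
            layer.params["W"][i] = w0 + eps
            lp = net.loss_and_param_grads(x, y)
            layer.params["W"][i] = w0 - eps
            lm = net.loss_and_param_grads(x, y)
            layer.params["W"][i] = w0
            assert abs((lp - lm) / (2 * eps) - gW[i]) < 1e-3

    def test_serialization_roundtrip_bitwise(self, tmp_path, rng):
        net = ConvNet(6, 64, 3, **TINY, seed=0)
        x = rng.normal(size=(4, 6, 64)).astype(np.float32)
        y = np.eye(3, dtype=np.float32)[rng.integers(0, 3, 4)]
        opt = Adam(net.layers)
        for _ in range(3):
            net.loss_and_param_grads(x, y)
            opt.step()
        net.save(tmp_path / "net.npz")
        back = ConvNet.load(tmp_path / "net.npz")
        np.testing.assert_array_equal(net.predict_proba(x), back.predict_proba(x))


class TestSplitData:
    def test_holdout_partition_property(self):
        ep = make_epochs(n_subjects=10, n_conditions=3, trials_per_condition=4)
        cfg = TrainingConfig(holdout_subjects=2, test_fraction=0.2, seed=1)
        train, test = split_data(ep, cfg)
        assert train.n_trials + test.n_trials == ep.n_trials
        train_subj = set(train.subject_ids)
        test_subj = set(test.subject_ids)
        fully_held = test_subj - train_subj
        assert len(fully_held) == 2
        # no trial in both sets: data rows are unique random draws
        joined = np.concatenate([train.data, test.data]).reshape(ep.n_trials, -1)
        assert len(np.unique(joined, axis=0)) == ep.n_trials

    def test_stratified_proportions(self):
        ep = make_epochs(n_subjects=10, n_conditions=3, trials_per_condition=33)
        cfg = TrainingConfig(holdout_subjects=1, test_fraction=0.2, seed=0)
        _, test = split_data(ep, cfg)
        assert test.n_trials == pytest.approx(0.2 * ep.n_trials, abs=2)
        _, counts = np.unique(test.labels.astype(str), return_counts=True)
        props = counts / counts.sum()
        assert np.abs(props - 1 / 3).max() < 0.02

    def test_seeded_determinism(self):
        ep = make_epochs(n_subjects=6, trials_per_condition=5)
        cfg = TrainingConfig(holdout_subjects=1, seed=9)
        a_train, a_test = split_data(ep, cfg)
        b_train, b_test = split_data(ep, cfg)
        np.testing.assert_array_equal(a_test.data, b_test.data)
        np.testing.assert_array_equal(a_train.data, b_train.data)

    def test_too_many_holdout_subjects_rejected(self):
        ep = make_epochs(n_subjects=3)
        with pytest.raises(ValueError, match="holdout"):
            split_data(ep, TrainingConfig(holdout_subjects=3))


class TestTraining:
    def test_separable_data_learned_and_protocol_respected(self):
        ep = simulate_epochs(tiny_simulation(trials=10, noise=(0.5, 0.3)), seed=2)
        cfg = TrainingConfig(
            max_epochs=25, early_stop_patience=10, n_folds=2,
            holdout_subjects=1, batch_size=16, seed=2,
        )
        train, test = split_data(ep, cfg)
        spec = ModelSpec(conv_filters=(4, 8), kernel_size=9, dense_units=(16,))
        models = train_crossval(spec, train, cfg)
        assert len(models) == 2
        for m in models:
            hist = m.history_
            assert 0 < len(hist) <= cfg.max_epochs
            if len(hist) < cfg.max_epochs:  # early stop fired
                losses = [h["val_loss"] for h in hist]
                best = int(np.argmin(losses))
                assert len(hist) - 1 - best >= cfg.early_stop_patience
        report = evaluate(models, test)
        assert report.test_accuracy_mean > 0.6  # sharply separable fixture
        np.testing.assert_allclose(report.confusion.sum(axis=1), 1.0, atol=1e-9)

    def test_shuffled_labels_score_at_chance(self):
        ep = simulate_epochs(tiny_simulation(n_subjects=6, trials=10), seed=4)
        rng = np.random.default_rng(0)
        shuffled = ep.labels[rng.permutation(ep.n_trials)]
        est = EpochClassifier(
            spec=ModelSpec(conv_filters=(4, 8), kernel_size=9, dense_units=(16,)),
            max_epochs=5, batch_size=32, random_state=0,
        )
        est.fit(ep.data[:100], shuffled[:100])
        acc = est.score(ep.data[100:], shuffled[100:])
        assert 0.25 <= acc <= 0.45  # chance is 1/3 for three balanced classes


class TestEvaluate:
    class _Stub:
        def __init__(self, classes, fn):
            self.classes_ = np.array(classes, dtype=object)
            self._fn = fn

        def predict(self, X):
            return self._fn(X)

    def test_perfect_predictor(self):
        ep = make_epochs(n_conditions=3, trials_per_condition=4)
        stub = self._Stub(ep.conditions, lambda X: ep.labels)
        report = evaluate([stub], ep)
        assert report.test_accuracy_mean == 1.0
        np.testing.assert_array_equal(report.confusion, np.eye(3))

    def test_constant_predictor(self):
        ep = make_epochs(n_conditions=3, trials_per_condition=4)
        stub = self._Stub(
            ep.conditions, lambda X: np.array(["cond0"] * len(X), dtype=object)
        )
        report = evaluate([stub], ep)
        assert report.test_accuracy_mean == pytest.approx(1 / 3)
        np.testing.assert_array_equal(report.confusion[:, 0], np.ones(3))

    def test_label_mismatch_rejected(self):
        ep = make_epochs(n_conditions=3)
        stub = self._Stub(["x", "y"], lambda X: np.array(["x"] * len(X)))
        with pytest.raises(ValueError, match="classes"):
            evaluate([stub], ep)

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], make_epochs())
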