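import numpy as np
import pytest

from deephistoclass._nn import (HybridNet, bce_from_logits, mc_predict_probs,
                                normalize_images, sample_drop_weights_mask,
                                sigmoid, train_network)
from deephistoclass.config import desk_config
from deephistoclass.errors import ConfigError, DataError, TrainingError
from deephistoclass.model import HBNet, HBNetResults


class TestDropWeightsMask:
    def test_rate_zero_all_ones(self, rng):
        assert np.all(sample_drop_weights_mask((100,), 0.0, rng) == 1.0)

    def test_zero_fraction_matches_rate(self, rng):
        m = sample_drop_weights_mask((10000,), 0.3, rng)
        assert 0.28 <= (m == 0).mean() <= 0.32

    def test_mean_preserving_in_expectation(self, rng):
        w = 1.7
        masked = np.array([
            (sample_drop_weights_mask((1,), 0.3, rng)[0]) * w
            for _ in range(10000)])
        assert masked.mean() == pytest.approx(w, abs=0.05)

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ConfigError):
            sample_drop_weights_mask((4,), 1.0, rng)


class TestForwardPass:
    def _net(self, rate, seed=0):
        cfg = desk_config(drop_weight_rate=rate, fc_layer_sizes=(32, 32),
                          cnn_feature_dim=16, augment=False)
        return cfg, HybridNet(cfg, handcrafted_dim=4,
                              rng=np.random.default_rng(seed))

    def test_output_in_sigmoid_range(self, rng):
        cfg, net = self._net(0.3)
        x = normalize_images(rng.integers(0, 256, (2, 64, 64, 3)).astype(np.uint8))
        hc = rng.standard_normal((2, 4))
        p = net.forward_probs(x, hc, masks=net.sample_head_masks(rng))
        assert p.shape == (2, 8)
        assert np.all((p > 0) & (p < 1))

    def test_rate_zero_is_deterministic(self, rng):
        cfg, net = self._net(0.0)
        x = normalize_images(rng.integers(0, 256, (1, 64, 64, 3)).astype(np.uint8))
        hc = rng.standard_normal((1, 4))
        p = mc_predict_probs(net, x, hc, T=5, rng=np.random.default_rng(1))
        assert np.all(p[0, 0] == p[0])  # all T rows identical

    def test_rate_positive_passes_differ(self, rng):
        cfg, net = self._net(0.3)
        x = normalize_images(rng.integers(0, 256, (1, 64, 64, 3)).astype(np.uint8))
        hc = rng.standard_normal((1, 4))
        p = mc_predict_probs(net, x, hc, T=20, rng=np.random.default_rng(1))
        assert p[0].std(axis=0).max() > 0

    def test_fixed_seed_bitwise_identical_mc(self, rng):
        cfg, net = self._net(0.3)
        x = normalize_images(rng.integers(0, 256, (2, 64, 64, 3)).astype(np.uint8))
        hc = rng.standard_normal((2, 4))
        p1 = mc_predict_probs(net, x, hc, T=10, rng=np.random.default_rng(7))
        p2 = mc_predict_probs(net, x, hc, T=10, rng=np.random.default_rng(7))
        assert np.array_equal(p1, p2)


class TestGradients:
    def test_numerical_gradient_check(self):
        """Finite-difference check of backprop through the whole network."""
        cfg = desk_config(drop_weight_rate=0.0, fc_layer_sizes=(8,),
                          cnn_feature_dim=4, n_labels=2, augment=False)
        rng = np.random.default_rng(0)
        net = HybridNet(cfg, handcrafted_dim=3, rng=rng)
        x = rng.standard_normal((2, 64, 64, 3)) * 0.1
        hc = rng.standard_normal((2, 3))
        y = np.array([[1.0, 0.0], [0.0, 1.0]])

        def loss_fn():
            feats = net.trunk_features(x, train=True)
            hybrid = np.concatenate([feats, hc], axis=1)
            logits = net.head_logits(hybrid, masks=None, train=True)
            return bce_from_logits(logits, y), logits

        loss, logits = loss_fn()
        net.backward((sigmoid(logits) - y) / logits.size)
        # probe a handful of weights in different layers
        layers = net.parameters()
        for layer in (layers[0], layers[-2], layers[-1]):
            W = layer.W
            i, j = 0, 0
            eps = 1e-6
            orig = W[i, j]
            W[i, j] = orig + eps
            lp, _ = loss_fn()
            W[i, j] = orig - eps
            lm, _ = loss_fn()
            W[i, j] = orig
            num = (lp - lm) / (2 * eps)
            assert layer.dW[i, j] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestTraining:
    def _toy_data(self, rng, n=60):
        """Linearly separable 2-label toy set: each label lights one color
        channel across the whole image (plus pixel noise)."""
        Y = rng.integers(0, 2, (n, 2))
        X = np.full((n, 64, 64, 3), 30, dtype=np.int16)
        X[Y[:, 0] == 1, :, :, 0] = 220
        X[Y[:, 1] == 1, :, :, 1] = 220
        X = np.clip(X + rng.integers(-10, 10, X.shape), 0, 255).astype(np.uint8)
        HC = np.zeros((n, 2))
        return X, HC, Y

    def test_loss_decreases_and_separable_data_learned(self, rng):
        X, HC, Y = self._toy_data(rng, n=80)
        cfg = desk_config(epochs=25, fc_layer_sizes=(32,), cnn_feature_dim=8,
                          n_labels=2, learning_rate=3e-3, augment=False)
        net = HybridNet(cfg, handcrafted_dim=2, rng=np.random.default_rng(1))
        _, log = train_network(net, normalize_images(X[:60]), HC[:60], Y[:60],
                               normalize_images(X[60:]), HC[60:], Y[60:],
                               cfg, np.random.default_rng(1))
        assert log[-1]["loss"] < log[0]["loss"]
        p = net.forward_probs(normalize_images(X[60:]), HC[60:], masks=None)
        em = np.mean(np.all((p >= 0.5) == (Y[60:] >= 0.5), axis=1))
        assert em >= 0.9

    def test_identical_seeds_identical_logs(self, rng):
        X, HC, Y = self._toy_data(rng, n=40)
        cfg = desk_config(epochs=3, fc_layer_sizes=(16,), cnn_feature_dim=8,
                          n_labels=2, augment=False)
        logs = []
        for _ in range(2):
            net = HybridNet(cfg, handcrafted_dim=2, rng=np.random.default_rng(5))
            _, log = train_network(net, normalize_images(X[:30]), HC[:30],
                                   Y[:30], normalize_images(X[30:]), HC[30:],
                                   Y[30:], cfg, np.random.default_rng(5))
            logs.append(log)
        assert logs[0] == logs[1]

    def test_divergence_aborts_with_diagnostic(self, rng):
        X, HC, Y = self._toy_data(rng, n=40)
        cfg = desk_config(epochs=2, fc_layer_sizes=(16,), cnn_feature_dim=8,
                          n_labels=2, learning_rate=1e-3, augment=False)
        net = HybridNet(cfg, handcrafted_dim=2, rng=np.random.default_rng(2))
        net.head[-1].b += np.inf  # force a non-finite loss
        with pytest.raises(TrainingError, match="non-finite"):
            train_network(net, normalize_images(X[:30]), HC[:30], Y[:30],
                          normalize_images(X[30:]), HC[30:], Y[30:],
                          cfg, np.random.default_rng(2))


class TestHBNetResults:
    def test_fit_produces_log_and_thresholds(self, tiny_fit):
        model, res = tiny_fit
        assert len(res.training_log) == model.config.epochs
        assert res.best_val_accuracy == res.training_log["val_accuracy"].max()
        assert res.thresholds.prob_thresholds.shape == (8,)
        assert "Hybrid Bayesian network" in res.summary()

    def test_mc_predict_shape_and_determinism(self, tiny_fit):
        model, res = tiny_fit
        test = model.splits["test"][:3]
        mc1 = res.mc_predict(test, T=8, seed=4)
        mc2 = res.mc_predict(test, T=8, seed=4)
        assert mc1[0].samples.shape == (8, 8)
        for a, b in zip(mc1, mc2):
            assert np.array_equal(a.samples, b.samples)

    def test_score_and_evaluate(self, tiny_fit):
        model, res = tiny_fit
        test = model.splits["test"]
        mc = res.mc_predict(test, T=10, seed=1)
        Y = np.stack([im.label_vector() for im in test])
        table = res.score(mc, y_true=Y)
        assert len(table) == len(test) * 8
        rep = res.evaluate(test, T=10, seed=1)
        assert 0.0 <= rep.hamming_loss <= 1.0

    def test_checkpoint_round_trip(self, tiny_fit, tmp_path):
        model, res = tiny_fit
        path = tmp_path / "model.npz"
        res.save(path)
        back = HBNetResults.load(path)
        test = model.splits["test"][:2]
        np.testing.assert_allclose(back.predict_proba(test),
                                   res.predict_proba(test), atol=1e-12)

    def test_duplicate_ids_rejected(self, small_dataset):
        images, _, _ = small_dataset
        dup = [images[0], images[0]] + images[1:]
        with pytest.raises(DataError):
            HBNet(dup)

    def test_empty_split_rejected(self, small_dataset):
        images, _, _ = small_dataset
        train_only = [im for im in images if im.split == "train"]
        with pytest.raises(DataError):
            HBNet(train_only)
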