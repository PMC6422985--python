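"""CNN building blocks: shape propagation, determinism, learning sanity."""

import numpy as np
import pytest

from ctgrp.cnn import (CNNModel, LayerSpec, TrainConfig, architecture_from_code,
                       build, conv_output_size, default_architecture, predict, train)


class TestShapes:
    @pytest.mark.parametrize("args,expected", [
        ((64, 5, 1, 0), 60),
        ((60, 3, 2, 0), 29),
        ((29, 5, 1, 0), 25),
        ((25, 3, 2, 0), 12),
        ((17, 1, 1, 0), 17),    # identity kernel
    ])
    def test_conv_output_size(self, args, expected):
        assert conv_output_size(*args) == expected

    def test_window_must_fit(self):
        with pytest.raises(ValueError):
            conv_output_size(3, 5, 1, 0)

    def test_default_architecture_feature_trace(self):
        model = build(default_architecture(), seed=0)
        trace = model.feature_map_trace()
        assert trace[0] == (64, 64, 3)
        spatial = [s for s in trace if len(s) == 3]
        assert (60, 60, 8) in spatial
        assert (29, 29, 8) in spatial
        assert (25, 25, 8) in spatial
        assert (12, 12, 8) in spatial
        dense = [s for s in trace if len(s) == 1]
        assert (144,) in dense and dense[-1] == (2,)

    def test_first_conv_parameter_count(self):
        model = build(default_architecture(), seed=0)
        conv1 = model.layers[0]
        assert conv1.params["W"].size + conv1.params["b"].size == 5 * 5 * 3 * 8 + 8

    def test_pooling_larger_than_input_is_shape_error(self):
        arch = [LayerSpec("input", size=8, channels=3),
                LayerSpec("convolution", kernel=5, n_filters=8),
                LayerSpec("average-pool", kernel=9, stride=2),
                LayerSpec("fully-connected", units=2),
                LayerSpec("softmax-output")]
        with pytest.raises(ValueError, match="layer 3"):
            build(arch, seed=0)

    def test_architecture_code_family(self):
        assert len(architecture_from_code(5)) < len(architecture_from_code(8))
        with pytest.raises(ValueError):
            architecture_from_code(13)


class TestForward:
    def test_softmax_rows_sum_to_one(self):
        model = build(default_architecture(), seed=1)
        x = np.random.default_rng(0).random((7, 64, 64, 3))
        proba = model.predict_proba(x)
        assert proba.shape == (7, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_parameters(self):
        a, b = build(default_architecture(), seed=9), build(default_architecture(), seed=9)
        for la, lb in zip(a.layers, b.layers):
            for key in la.params:
                np.testing.assert_array_equal(la.params[key], lb.params[key])

    def test_duplicate_inputs_get_identical_rows(self):
        model = build(default_architecture(), seed=2)
        x = np.random.default_rng(1).random((1, 64, 64, 3))
        proba = model.predict_proba(np.concatenate([x, x]))
        np.testing.assert_array_equal(proba[0], proba[1])

    def test_prediction_deterministic(self):
        model = build(default_architecture(), seed=3)
        x = np.random.default_rng(2).random((4, 64, 64, 3))
        p1, _ = predict(model, x)
        p2, _ = predict(model, x)
        np.testing.assert_array_equal(p1, p2)

    def test_wrong_shape_rejected(self):
        model = build(default_architecture(), seed=0)
        with pytest.raises(ValueError, match="shape"):
            model.predict_proba(np.zeros((2, 32, 32, 3)))


def separable_images(n_per_class=100, seed=0):
    """Bright-top vs bright-bottom images: linearly separable by design."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls, name in ((0, "normal"), (1, "pathological")):
        for _ in range(n_per_class):
            img = rng.random((64, 64)) * 0.2
            if cls == 0:
                img[:32] += 0.6
            else:
                img[32:] += 0.6
            xs.append(img)
            ys.append(name)
    return np.stack(xs), ys


class TestTraining:
    def test_separable_set_reaches_high_accuracy(self):
        x, y = separable_images(100, seed=4)
        model = build(default_architecture(), seed=4)
        train(model, x, y, config=TrainConfig(seed=4))
        _, acc = model.evaluate(x, y)
        assert acc >= 0.95

    def test_loss_decreases_on_separable_set(self):
        x, y = separable_images(100, seed=5)
        model = build(default_architecture(), seed=5)
        train(model, x, y, config=TrainConfig(seed=5))
        assert model.history[-1]["train_loss"] <= model.history[0]["train_loss"]

    def test_training_fully_deterministic(self):
        x, y = separable_images(30, seed=6)
        cfg = TrainConfig(seed=6, max_epochs=2)
        m1 = train(build(default_architecture(), seed=6), x, y, config=cfg)
        m2 = train(build(default_architecture(), seed=6), x, y, config=cfg)
        for la, lb in zip(m1.layers, m2.layers):
            for key in la.params:
                np.testing.assert_array_equal(la.params[key], lb.params[key])

    def test_single_class_rejected(self):
        x, _ = separable_images(10, seed=7)
        model = build(default_architecture(), seed=7)
        with pytest.raises(ValueError, match="single class"):
            train(model, x, ["normal"] * len(x), config=TrainConfig(seed=7))

    def test_gradient_step_reduces_loss(self):
        """Without dropout/L2, small plain-SGD steps lower the fitted loss."""
        arch = architecture_from_code("I-C-P-F-O", drop_prob=0.0)
        cfg = TrainConfig(max_epochs=1, batch_size=2, learning_rate=1e-4,
                          l2_factor=0.0, optimizer="sgd", sgd_momentum=0.0)
        for seed in (0, 1, 2):
            xs, ys = separable_images(1, seed=seed + 50)  # one image per class
            m = build(arch, seed=seed)
            l0 = m.evaluate(xs, ys)[0]
            m.fit(xs, ys, config=cfg)
            l1 = m.evaluate(xs, ys)[0]
            assert l1 < l0

    @pytest.mark.parametrize("opt", ["sgd", "rmsp"])
    def test_alternative_optimizers_run(self, opt):
        x, y = separable_images(20, seed=9)
        model = build(architecture_from_code(5), seed=9)
        train(model, x, y, config=TrainConfig(seed=9, max_epochs=2, optimizer=opt))
        assert len(model.history) == 2


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path):
        x, y = separable_images(20, seed=10)
        model = train(build(default_architecture(), seed=10), x, y,
                      config=TrainConfig(seed=10, max_epochs=1))
        p1, _ = model.predict(x[:5])
        path = tmp_path / "model.npz"
        model.save(path)
        back = CNNModel.load(path)
        p2, _ = back.predict(x[:5])
        np.testing.assert_array_equal(p1, p2)
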