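"""Classifier construction, class weighting, scheduling, augmentation,
training contracts."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from bacscan import detector
from bacscan.detector import (FULL_BACKBONE, AugmentConfig, ModelConfig,
                              TrainConfig, augment, build_model, class_weights,
                              lr_schedule, predict, train)
from bacscan.nn import Conv2d, Dense, MaxPool2d, Sigmoid


def toy_config(n_finetune=2):
    return ModelConfig(input_size=(32, 32), backbone_widths=((4,), (8,)),
                       n_finetune_conv_layers=n_finetune, head_units=16)


def toy_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 0.1, (n, 32, 32)).astype(np.float32)
    y = np.zeros(n)
    y[: n // 2] = 1
    for i in range(n // 2):
        r, c = rng.integers(4, 24, 2)
        x[i, r:r + 6, c:c + 6] += 2.0
    return x, y


class TestBuildModel:
    def test_full_profile_structure(self):
        cfg = ModelConfig(input_size=(64, 32), backbone_widths=FULL_BACKBONE)
        model = build_model(cfg, np.random.default_rng(0))
        convs = [l for l in model.layers if isinstance(l, Conv2d)]
        pools = [l for l in model.layers if isinstance(l, MaxPool2d)]
        denses = [l for l in model.layers if isinstance(l, Dense)]
        assert len(convs) == 13
        assert len(pools) == 5
        assert [d.w.value.shape[1] for d in denses] == [256, 256, 1]
        assert isinstance(model.layers[-1], Sigmoid)

    def test_finetune_zero_freezes_all_convs(self):
        model = build_model(toy_config(n_finetune=0), np.random.default_rng(0))
        for l in model.layers:
            if isinstance(l, Conv2d):
                assert not l.trainable
            if isinstance(l, Dense):
                assert l.trainable

    def test_finetune_marks_deepest_convs(self):
        cfg = ModelConfig(input_size=(64, 32), backbone_widths=FULL_BACKBONE,
                          n_finetune_conv_layers=5)
        model = build_model(cfg, np.random.default_rng(0))
        flags = [l.trainable for l in model.layers if isinstance(l, Conv2d)]
        assert flags == [False] * 8 + [True] * 5

    def test_frozen_layers_unchanged_after_step(self):
        x, y = toy_data(16, seed=1)
        model = build_model(toy_config(n_finetune=1), np.random.default_rng(2))
        frozen_before = [l.w.value.copy() for l in model.layers
                         if isinstance(l, Conv2d) and not l.trainable]
        trainable_before = [l.w.value.copy() for l in model.layers
                            if isinstance(l, Conv2d) and l.trainable]
        cfg = TrainConfig(epochs=1, batch_size=8, lr0=1e-2, seed=0,
                          augmentation=AugmentConfig(rotation_deg=0, shift_frac=0,
                                                     zoom_frac=0, hflip=False,
                                                     vflip=False,
                                                     gaussian_sd_frac=0,
                                                     salt_pepper_frac=0))
        train(model, (x, y), (x, y), cfg)
        frozen_after = [l.w.value for l in model.layers
                        if isinstance(l, Conv2d) and not l.trainable]
        for b, a in zip(frozen_before, frozen_after):
            np.testing.assert_array_equal(b, a)
        changed = [not np.array_equal(b, a) for b, a in
                   zip(trainable_before,
                       [l.w.value for l in model.layers
                        if isinstance(l, Conv2d) and l.trainable])]
        assert any(changed)

    def test_output_is_probability(self):
        model = build_model(toy_config(), np.random.default_rng(3))
        x = np.random.default_rng(0).normal(0, 1, (2, 32, 32, 3)).astype(np.float32)
        p = model.forward(x)
        assert p.shape == (2, 1)
        assert np.all((p > 0) & (p < 1))


class TestClassWeights:
    def test_balanced(self):
        assert class_weights([0] * 50 + [1] * 50) == (1.0, 1.0)

    def test_75_25(self):
        w_neg, w_pos = class_weights([0] * 75 + [1] * 25)
        assert w_neg == pytest.approx(2 / 3)
        assert w_pos == pytest.approx(2.0)

    def test_ratio_identity(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        w_neg, w_pos = class_weights(y)
        assert w_pos / w_neg == pytest.approx((y == 0).sum() / (y == 1).sum())

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])


class TestLrSchedule:
    def test_endpoints_and_midpoint(self):
        cfg = TrainConfig(epochs=25, lr0=1e-6)
        assert lr_schedule(0, cfg) == pytest.approx(1e-6)
        assert lr_schedule(24, cfg) == pytest.approx(0.0, abs=1e-20)
        assert lr_schedule(12, cfg) == pytest.approx(5e-7)

    def test_monotone_non_increasing(self):
        cfg = TrainConfig(epochs=25, lr0=1e-3)
        lrs = [lr_schedule(t, cfg) for t in range(25)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_out_of_range(self):
        cfg = TrainConfig(epochs=10)
        with pytest.raises(ValueError):
            lr_schedule(10, cfg)
        with pytest.raises(ValueError):
            lr_schedule(-1, cfg)


class TestAugment:
    ZERO = AugmentConfig(rotation_deg=0, shift_frac=0, zoom_frac=0,
                         hflip=False, vflip=False, gaussian_sd_frac=0,
                         salt_pepper_frac=0)

    def test_zero_config_is_bitwise_identity(self, rng):
        img = rng.normal(0, 1, (32, 16)).astype(np.float32)
        out = augment(img, self.ZERO, rng)
        assert out is img or np.array_equal(out, img)

    def test_flip_involution(self, rng):
        cfg = AugmentConfig(rotation_deg=0, shift_frac=0, zoom_frac=0,
                            hflip=True, vflip=False, gaussian_sd_frac=0,
                            salt_pepper_frac=0)
        img = rng.normal(0, 1, (32, 16)).astype(np.float32)
        # find a draw that flips, apply twice with identical streams
        out1 = augment(img, cfg, np.random.default_rng(42))
        out2 = augment(out1, cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(out2, img)

    def test_salt_pepper_binomial_count(self):
        cfg = AugmentConfig(rotation_deg=0, shift_frac=0, zoom_frac=0,
                            hflip=False, vflip=False, gaussian_sd_frac=0,
                            salt_pepper_frac=0.01)
        rng = np.random.default_rng(0)
        img = rng.normal(0.5, 0.05, (100, 100)).astype(np.float32)
        out = augment(img, cfg, np.random.default_rng(1))
        n_changed = (out != img).sum()
        se = np.sqrt(1e4 * 0.01 * 0.99)
        assert abs(n_changed - 100) <= 3 * se

    def test_shape_preserved(self, rng):
        cfg = AugmentConfig()
        img = rng.normal(0, 1, (32, 16, 3)).astype(np.float32)
        assert augment(img, cfg, rng).shape == (32, 16, 3)


class TestTrain:
    def test_separable_toy_reaches_high_auc_pr(self):
        x, y = toy_data(60, seed=0)
        model = build_model(toy_config(), np.random.default_rng(1))
        cfg = TrainConfig(epochs=10, batch_size=8, lr0=1e-3, seed=0)
        tm = train(model, (x[::2], y[::2]), (x[1::2], y[1::2]), cfg)
        s = predict(model, x[::2])
        assert average_precision_score(y[::2], s) > 0.95
        assert s[y[::2] == 1].mean() > s[y[::2] == 0].mean()
        assert tm.selected_epoch == int(np.argmax(
            [h["val_auc_pr"] for h in tm.history]))

    def test_equal_weights_match_unweighted_loss(self):
        from bacscan.detector import _weighted_bce

        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 50)
        y = rng.integers(0, 2, 50).astype(float)
        w = np.ones(50)
        unweighted = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert _weighted_bce(p, y, w) == pytest.approx(unweighted)

    def test_training_reproducible(self):
        x, y = toy_data(24, seed=2)
        runs = []
        for _ in range(2):
            model = build_model(toy_config(), np.random.default_rng(5))
            cfg = TrainConfig(epochs=2, batch_size=8, lr0=1e-3, seed=7)
            tm = train(model, (x, y), (x, y), cfg)
            runs.append((tm.history, model.get_weights()))
        assert runs[0][0] == runs[1][0]
        for a, b in zip(runs[0][1], runs[1][1]):
            np.testing.assert_array_equal(a, b)

    def test_checkpoint_reload_reproduces_val_auc(self):
        x, y = toy_data(40, seed=3)
        model = build_model(toy_config(), np.random.default_rng(8))
        cfg = TrainConfig(epochs=4, batch_size=8, lr0=1e-3, seed=3)
        tm = train(model, (x, y), (x, y), cfg)
        fresh = build_model(toy_config(), np.random.default_rng(99))
        fresh.set_weights(tm.weights)
        s = predict(fresh, x)
        best = max(h["val_auc_pr"] for h in tm.history)
        assert average_precision_score(y, s) == pytest.approx(best, abs=1e-6)


class TestPredict:
    def test_deterministic_and_order_preserving(self):
        x, y = toy_data(10, seed=4)
        model = build_model(toy_config(), np.random.default_rng(2))
        s1 = predict(model, x)
        s2 = predict(model, x)
        np.testing.assert_array_equal(s1, s2)
        perm = np.random.default_rng(0).permutation(10)
        np.testing.assert_allclose(predict(model, x[perm]), s1[perm], rtol=1e-6)
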