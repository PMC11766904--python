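"""Architecture audit, training behaviour, and determinism of the CNN."""

import numpy as np
import pytest

from eegdem.cnn import (
    CNN,
    ModelConfig,
    build_model,
    load_model,
    predict,
    save_model,
    train,
)


def blobs(n_per_class, size=24, n_classes=2, seed=0):
    """Linearly separable image classes: class k lights up stripe k."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    stripe = size // n_classes
    for k in range(n_classes):
        x = rng.random((n_per_class, size, size, 3)).astype(np.float32) * 0.3
        x[:, k * stripe:(k + 1) * stripe, :, :] += 0.6
        xs.append(x)
        ys.append(np.full(n_per_class, k))
    return np.concatenate(xs), np.concatenate(ys)


def small_config(**kw):
    defaults = dict(input_size=(24, 24, 3), n_classes=2, train_epochs=20,
                    batch_size=8, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestConfig:
    def test_defaults_match_protocol(self):
        cfg = ModelConfig()
        assert cfg.input_size == (150, 150, 3)
        assert cfg.conv_filters == (32, 64, 128)
        assert cfg.kernel == (3, 3) and cfg.leaky_alpha == 0.1
        assert cfg.dropouts == (0.25, 0.25, 0.4)
        assert cfg.dense_units == 128 and cfg.dense_dropout == 0.3
        assert cfg.train_epochs == 100

    @pytest.mark.parametrize("kw", [
        {"n_classes": 1},
        {"leaky_alpha": 0.0},
        {"dropouts": (0.25, 0.25, 1.0)},
        {"input_size": (8, 8, 3)},   # collapses before the third block
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            build_model(ModelConfig(**kw))


class TestArchitecture:
    def test_layer_sequence(self):
        model = CNN(ModelConfig())
        names = [layer.name for layer in model.layers]
        assert names == (["conv", "leaky_relu", "maxpool", "dropout"] * 3
                         + ["flatten", "dense", "leaky_relu", "dropout",
                            "dense"])

    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_final_layer_width_and_softmax(self, n_classes):
        model = CNN(ModelConfig(n_classes=n_classes))
        assert model.layers[-1].w.shape[1] == n_classes
        probs = predict(model, np.zeros((4, 150, 150, 3), dtype=np.float32))
        assert probs.shape == (4, n_classes)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_audit_150_input(self):
        # valid 3×3 convs + same-padded 2×2 pools:
        # 150→148→74→72→36→34→17 spatially, 128 maps before flatten
        model = CNN(ModelConfig())
        shapes = dict((f"{n}{i}", s) for i, (n, s)
                      in enumerate(model.output_shapes()))
        pools = [s for (n, s) in model.output_shapes() if n == "maxpool"]
        assert pools == [(74, 74, 32), (36, 36, 64), (17, 17, 128)]
        flat = [s for (n, s) in model.output_shapes() if n == "flatten"][0]
        assert flat == (17 * 17 * 128,)

    def test_parameter_count_matches_hand_computation(self):
        # conv: (3·3·cin+1)·cout; dense: (nin+1)·nout
        expected = ((3 * 3 * 3 + 1) * 32 + (3 * 3 * 32 + 1) * 64
                    + (3 * 3 * 64 + 1) * 128
                    + (17 * 17 * 128 + 1) * 128 + (128 + 1) * 2)
        assert CNN(ModelConfig()).n_parameters() == expected


class TestTraining:
    def test_memorizes_a_small_set(self):
        x, y = blobs(10)
        cfg = small_config(train_epochs=40)
        _, report = train(build_model(cfg), x, y, cfg)
        assert len(report.loss) == cfg.train_epochs
        assert report.accuracy[-1] >= 0.95
        assert report.loss[-1] < report.loss[0]

    def test_single_class_training_rejected(self):
        x, _ = blobs(5)
        cfg = small_config()
        with pytest.raises(ValueError, match="single class"):
            train(build_model(cfg), x, np.zeros(10, dtype=int), cfg)

    def test_same_seed_identical_runs(self):
        x, y = blobs(6)
        cfg = small_config(train_epochs=5)
        _, r1 = train(build_model(cfg), x, y, cfg)
        _, r2 = train(build_model(cfg), x, y, cfg)
        assert r1.loss == r2.loss         # bit-exact numpy determinism
        assert r1.accuracy == r2.accuracy

    def test_labels_independent_of_features_stay_at_chance_on_holdout(self):
        # null calibration: when labels carry no information about the
        # images, held-out accuracy must sit in the binomial chance band
        rng = np.random.default_rng(0)
        x = rng.random((40, 24, 24, 3), dtype=np.float32)
        y = rng.integers(0, 2, 40)
        x_te = rng.random((100, 24, 24, 3), dtype=np.float32)
        y_te = rng.integers(0, 2, 100)
        cfg = small_config(train_epochs=10)
        model, _ = train(build_model(cfg), x, y, cfg)
        acc = (predict(model, x_te).argmax(1) == y_te).mean()
        half = 1.96 * np.sqrt(0.25 / len(y_te))   # ±0.098 at n = 100
        assert abs(acc - 0.5) <= half + 1e-9


class TestPrediction:
    def test_probability_rows_normalized_any_batch(self):
        model = build_model(small_config())
        x = np.random.default_rng(1).random((7, 24, 24, 3)).astype(np.float32)
        probs = predict(model, x, batch_size=3)
        assert probs.shape == (7, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_order_equivariance(self):
        model = build_model(small_config())
        x = np.random.default_rng(2).random((10, 24, 24, 3)).astype(np.float32)
        perm = np.random.default_rng(3).permutation(10)
        assert np.allclose(predict(model, x)[perm], predict(model, x[perm]),
                           atol=1e-6)

    def test_confident_on_separable_data(self):
        x, y = blobs(10)
        cfg = small_config(train_epochs=30)
        model, _ = train(build_model(cfg), x, y, cfg)
        x_te, y_te = blobs(10, seed=5)
        probs = predict(model, x_te)
        assert (probs.argmax(1) == y_te).mean() > 0.9
        assert probs.max(axis=1).mean() > 0.5


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        x, y = blobs(4)
        cfg = small_config(train_epochs=2)
        model, _ = train(build_model(cfg), x, y, cfg)
        path = save_model(model, str(tmp_path / "model.npz"))
        clone = load_model(path)
        assert clone.config == model.config
        assert np.allclose(predict(clone, x), predict(model, x))

    def test_train_report_export(self, tmp_path):
        x, y = blobs(4)
        x_va, y_va = blobs(3, seed=8)
        cfg = small_config(train_epochs=3)
        _, report = train(build_model(cfg), x, y, cfg,
                          validation=(x_va, y_va))
        assert len(report.val_loss) == len(report.val_accuracy) == 3
        path = report.to_tsv(str(tmp_path / "report.tsv"))
        import pandas as pd

        frame = pd.read_csv(path, sep="\t")
        assert list(frame.columns) == ["epoch", "loss", "accuracy",
                                       "val_loss", "val_accuracy"]
        assert len(frame) == 3
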