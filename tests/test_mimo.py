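import numpy as np
import pytest

from vitispec import mimo
from vitispec.mimo import (
    ArchitectureSpec,
    ChannelScaler,
    TrainingConfig,
    build_network,
    stack_channels,
)


@pytest.fixture(scope="module")
def toy_problem():
    """Tiny near-linear regression task the network can fit quickly."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((48, 16, 3)).astype(np.float32)
    W = rng.standard_normal((16 * 3, 3))
    Y = X.reshape(48, -1) @ W * 0.1 + np.array([18.0, 3.2, 8.0])
    return X, Y


class TestStackChannels:
    def test_shape_and_channel_order(self, small_lib):
        X3 = stack_channels(small_lib)
        assert X3.shape == (len(small_lib), len(small_lib.grid), 3)
        from vitispec import pretreat

        np.testing.assert_array_equal(
            X3[:, :, 0], pretreat.apply_source(small_lib, "REF")
        )
        np.testing.assert_array_equal(
            X3[:, :, 1], pretreat.apply_source(small_lib, "ABS_SNV")
        )
        np.testing.assert_array_equal(
            X3[:, :, 2], pretreat.apply_source(small_lib, "ABS_SG1")
        )

    def test_snv_channel_rows_zero_mean(self, small_lib):
        X3 = stack_channels(small_lib)
        np.testing.assert_allclose(X3[:, :, 1].mean(axis=1), 0, atol=1e-12)

    def test_channel_order_changes_predictions(self, small_lib):
        """Channels are not interchangeable for a built network."""
        X3 = stack_channels(small_lib)
        X3 = ChannelScaler().fit(X3).transform(X3)
        model = build_network(len(small_lib.grid), seed=0)
        base = model.predict(X3)
        permuted = model.predict(X3[:, :, [2, 0, 1]])
        assert not np.allclose(base, permuted)

    def test_scaler_fits_on_calibration_only(self, small_lib):
        X3 = stack_channels(small_lib)
        scaler = ChannelScaler().fit(X3[:10])
        out = scaler.transform(X3[:10])
        np.testing.assert_allclose(out.mean(axis=(0, 1)), 0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=(0, 1)), 1, atol=1e-6)


class TestArchitecture:
    def test_table_shape_pipeline_for_L216(self):
        model = build_network(216, seed=0)
        x = np.random.default_rng(0).random((2, 216, 3)).astype(np.float32)
        shapes = []
        out = x
        for layer in model.trunk.layers:
            out = layer.forward(out, False, None)
            shapes.append(out.shape[1:])
        assert shapes == [
            (216, 3),      # attention keeps (L, D)
            (216, 128),    # conv 128 x k5
            (216, 128),    # dropout
            (108, 128),    # pool 2
            (108, 64),     # conv 64 x k7
            (108, 64),     # dropout
            (54, 64),      # pool 2
            (54, 32),      # conv 32 x k7
            (1728,),       # flatten 54*32
            (128,), (64,), (32,),
        ]
        assert model.flat_width == 1728

    def test_three_named_outputs(self):
        model = build_network(64, seed=0)
        assert mimo.OUTPUT_NAMES == ("brix", "ph", "ta")
        assert len(model.heads) == 3
        x = np.zeros((3, 64, 3), dtype=np.float32)
        assert model.predict(x).shape == (3, 3)

    def test_eight_attention_heads_softmax_normalized(self):
        model = build_network(32, seed=0)
        x = np.random.default_rng(1).random((4, 32, 3)).astype(np.float32)
        att = model.attention_weights(x)
        assert att.shape == (4, 8, 32, 32)
        assert att.min() >= 0
        np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-5)

    def test_seeded_builds_have_identical_weights(self):
        w1 = build_network(32, seed=42).get_weights()
        w2 = build_network(32, seed=42).get_weights()
        for a, b in zip(w1, w2):
            for k in a:
                np.testing.assert_array_equal(a[k], b[k])

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_network(4)

    def test_l2_regularizer_is_live(self):
        base = build_network(16, seed=3)
        unreg = mimo.AttentionCNN(16, 3, ArchitectureSpec(conv_l2=0.0), seed=3)
        assert base.trunk.penalty() > 0
        assert unreg.trunk.penalty() == 0
        # identical initial weights, different gradients through the penalty
        x = np.random.default_rng(0).random((4, 16, 3)).astype(np.float32)
        for m in (base, unreg):
            pred = m._forward(x, False, None)
            m._backward(np.ones_like(pred) / 4)
        gb = base.trunk.layers[1].grads["W"]
        gu = unreg.trunk.layers[1].grads["W"]
        np.testing.assert_allclose(
            gb - gu, 2 * 0.01 * base.trunk.layers[1].params["W"], atol=1e-6
        )


class TestTraining:
    def test_loss_decreases_on_toy_problem(self, toy_problem):
        X, Y = toy_problem
        model = build_network(16, seed=1)
        hist = mimo.train(
            model, X, Y,
            TrainingConfig(epochs=30, batch_size=16, val_fraction=0.0, seed=1),
        )
        assert hist["loss_total"].iloc[-1] < hist["loss_total"].iloc[0]
        # history carries the per-output loss columns
        assert {"loss_brix", "loss_ph", "loss_ta"} <= set(hist.columns)

    def test_training_is_seed_deterministic(self, toy_problem):
        X, Y = toy_problem
        preds = []
        for _ in range(2):
            model = build_network(16, seed=2)
            mimo.train(model, X, Y,
                       TrainingConfig(epochs=5, batch_size=16, seed=2))
            preds.append(model.predict(X))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_predictions_destandardized_to_target_scale(self, toy_problem):
        X, Y = toy_problem
        model = build_network(16, seed=1)
        mimo.train(model, X, Y,
                   TrainingConfig(epochs=20, batch_size=16,
                                  val_fraction=0.0, seed=1))
        pred = model.predict(X)
        # after fitting, predictions live near the raw target scales
        assert abs(pred[:, 0].mean() - Y[:, 0].mean()) < 2.0
        assert abs(pred[:, 1].mean() - Y[:, 1].mean()) < 0.5

    def test_predict_is_permutation_equivariant(self, toy_problem):
        X, Y = toy_problem
        model = build_network(16, seed=1)
        mimo.train(model, X, Y, TrainingConfig(epochs=2, seed=1))
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_allclose(
            model.predict(X[perm]), model.predict(X)[perm], atol=1e-5
        )

    def test_repeated_predict_identical(self, toy_problem):
        X, Y = toy_problem
        model = build_network(16, seed=1)
        mimo.train(model, X, Y, TrainingConfig(epochs=2, seed=1))
        np.testing.assert_array_equal(model.predict(X), model.predict(X))

    def test_early_stopping_restores_best_weights(self, toy_problem):
        X, Y = toy_problem
        model = build_network(16, seed=4)
        hist = mimo.train(
            model, X, Y,
            TrainingConfig(epochs=60, batch_size=16, patience=5,
                           val_fraction=0.2, seed=4),
        )
        assert "val_loss_total" in hist.columns
        assert len(hist) <= 60

    def test_shape_mismatch_rejected(self, toy_problem):
        X, Y = toy_problem
        model = build_network(16, seed=1)
        mimo.train(model, X, Y, TrainingConfig(epochs=1, seed=1))
        with pytest.raises(ValueError):
            model.predict(X[:, :8, :])


class TestCheckpoint:
    def test_save_load_round_trip(self, toy_problem, tmp_path):
        X, Y = toy_problem
        model = build_network(16, seed=1)
        mimo.train(model, X, Y, TrainingConfig(epochs=2, seed=1))
        path = tmp_path / "model.npz"
        mimo.save_model(model, path)
        back = mimo.load_model(path)
        np.testing.assert_array_equal(back.predict(X), model.predict(X))
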