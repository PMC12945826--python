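"""Tests for the NumPy network core: primitives, gradients, training contracts."""

import numpy as np
import pytest

from respmotion.nn import (
    BiLSTM,
    LSTM,
    NetConfig,
    RespMotionNet,
    composite_loss,
    dilated_conv_1d,
    receptive_field,
    train,
)
from respmotion.nn.model import _Adam
from respmotion.preprocess import WindowSpec, WindowedDataset
from respmotion.siggen import GeneratorConfig, generate_dataset
from respmotion.preprocess import build_windowed_dataset


def brute_force_dilated_conv(F, k, d):
    """Triple-loop oracle: out[p] = sum_i F[p - d*i] k[i], zero-padded."""
    F = np.asarray(F, dtype=float)
    k = np.asarray(k, dtype=float)
    out = np.zeros_like(F)
    for p in range(len(F)):
        acc = 0.0
        for i in range(len(k)):
            j = p - d * i
            if 0 <= j < len(F):
                acc += F[j] * k[i]
        out[p] = acc
    return out


class TestDilatedConv:
    def test_hand_evaluated_example(self):
        out = dilated_conv_1d([1, 2, 3, 4, 5], [1, 1, 1], d=2)
        np.testing.assert_allclose(out, [1, 2, 4, 6, 9])

    @pytest.mark.parametrize("d", [1, 2, 5])
    def test_identity_kernel(self, d):
        F = np.random.default_rng(0).normal(size=20)
        np.testing.assert_allclose(dilated_conv_1d(F, [1, 0, 0], d), F)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        F = rng.normal(size=50)
        k = rng.normal(size=3)
        out = dilated_conv_1d(F, k, d=4)
        assert np.max(np.abs(out - brute_force_dilated_conv(F, k, 4))) < 1e-9

    def test_d1_equals_standard_convolution(self):
        rng = np.random.default_rng(2)
        F = rng.normal(size=30)
        k = rng.normal(size=4)
        expected = np.convolve(F, k)[: len(F)]
        np.testing.assert_allclose(dilated_conv_1d(F, k, d=1), expected,
                                   atol=1e-12)

    def test_rejects_empty_input(self):
        with pytest.raises(ValueError):
            dilated_conv_1d([], [1], 1)
        with pytest.raises(ValueError):
            dilated_conv_1d([1, 2], [], 1)

    def test_receptive_field_by_impulse_response(self):
        kernel_size, dilations = 3, (1, 2, 4, 8)
        rng = np.random.default_rng(3)
        T = 64
        impulse = np.zeros(T)
        impulse[0] = 1.0
        h = impulse
        for d in dilations:
            k = rng.normal(size=kernel_size)
            k[0] += 1.0  # keep the zero-lag path alive
            h = dilated_conv_1d(h, k, d)
        support = np.flatnonzero(np.abs(h) > 1e-12)
        assert support[-1] + 1 == receptive_field(kernel_size, dilations)


class TestBiLSTM:
    def test_zero_parameters_give_zero_output(self):
        rng = np.random.default_rng(0)
        layer = BiLSTM(4, 8, rng, dtype=np.float64)
        for p in layer.params():
            p.value[...] = 0.0
        y = layer.forward(rng.normal(size=(2, 10, 4)))
        assert y.shape == (2, 10, 16)
        assert np.max(np.abs(y)) == 0.0

    def test_output_dimension_is_2h(self):
        rng = np.random.default_rng(1)
        layer = BiLSTM(3, 64, rng)
        y = layer.forward(rng.normal(size=(1, 5, 3)).astype(np.float32))
        assert y.shape[-1] == 128

    def test_time_reversal_symmetry(self):
        """The backward half equals a forward LSTM run on the reversed input."""
        rng = np.random.default_rng(3)
        bi = BiLSTM(4, 6, rng, dtype=np.float64)
        x = rng.normal(size=(2, 12, 4))
        y = bi.forward(x)
        oracle = bi.bwd.forward(x[:, ::-1])  # single-direction on reversed seq
        np.testing.assert_allclose(y[:, :, 6:], oracle[:, ::-1], atol=1e-12)

    def test_causality_of_directional_streams(self):
        rng = np.random.default_rng(4)
        bi = BiLSTM(2, 5, rng, dtype=np.float64)
        x = rng.normal(size=(1, 10, 2))
        y1 = bi.forward(x)
        x2 = x.copy()
        x2[0, 7:] += 1.0  # perturb the future
        y2 = bi.forward(x2)
        # forward half at t<7 must not change; backward half at t>=7 unaffected
        np.testing.assert_allclose(y1[0, :7, :5], y2[0, :7, :5], atol=1e-12)
        assert not np.allclose(y1[0, 7:, :5], y2[0, 7:, :5])


@pytest.fixture(scope="module")
def tiny_model():
    cfg = NetConfig(conv_channels=4, dilations=(1, 2), lstm_hidden=5,
                    latent_dim=3, reg_hidden=4, decoder_hidden=4,
                    spatial_dropout=0.0, dtype="float64", seed=0)
    return RespMotionNet(cfg, window_len=12, n_channels=4, n_horizons=2), cfg


class TestModelForward:
    def test_head_shapes_and_softmax_normalization(self, tiny_model):
        model, _ = tiny_model
        X = np.random.default_rng(0).random((5, 12, 4))
        out = model.forward(X)
        assert out["class_probs"].shape == (5, 4)
        np.testing.assert_allclose(out["class_probs"].sum(axis=1), 1.0,
                                   atol=1e-6)
        assert out["future"].shape == (5, 3, 2)
        assert out["recon"].shape == (5, 12, 3)
        assert np.all((out["excessive_prob"] >= 0) & (out["excessive_prob"] <= 1))
        assert out["z"].shape == (5, 3)

    def test_inference_is_deterministic(self, tiny_model):
        model, _ = tiny_model
        X = np.random.default_rng(1).random((3, 12, 4))
        o1 = model.forward(X)
        o2 = model.forward(X)
        for k in ("class_probs", "future", "recon", "excessive_prob"):
            assert np.array_equal(o1[k], o2[k])

    def test_rejects_wrong_window_shape(self, tiny_model):
        model, _ = tiny_model
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 10, 4)))

    def test_rejects_non_compressing_latent(self):
        cfg = NetConfig(latent_dim=100, dtype="float64")
        with pytest.raises(ValueError):
            RespMotionNet(cfg, window_len=8, n_channels=4, n_horizons=1)


class TestCompositeLoss:
    def _exact_case(self):
        preds = {
            "class_probs": np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]]),
            "future": np.array([[[0.1]] * 3, [[0.2]] * 3]),
            "recon": np.zeros((2, 4, 3)),
            "excessive_prob": np.array([0.0, 1.0]),
        }
        targets = {
            "class_index": np.array([0, 2]),
            "future": preds["future"].copy(),
            "recon": preds["recon"].copy(),
            "excessive": np.array([0.0, 1.0]),
        }
        return preds, targets

    def test_perfect_predictions_give_zero(self):
        preds, targets = self._exact_case()
        assert composite_loss(preds, targets, (1, 1, 1, 1)) == 0.0

    def test_reconstruction_only_weights(self):
        preds, targets = self._exact_case()
        preds["recon"] = preds["recon"] + 0.25
        loss = composite_loss(preds, targets, (0, 0, 1, 0))
        assert loss == pytest.approx(0.25)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(2)
        B, W, NH = 4, 8, 2
        preds = {
            "class_probs": rng.dirichlet(np.ones(4), size=B),
            "future": rng.random((B, 3, NH)),
            "recon": rng.random((B, W, 3)),
            "excessive_prob": rng.uniform(0.01, 0.99, B),
        }
        targets = {
            "class_index": rng.integers(0, 4, B),
            "future": rng.random((B, 3, NH)),
            "recon": rng.random((B, W, 3)),
            "excessive": rng.integers(0, 2, B).astype(float),
        }
        w = (0.7, 1.3, 2.0, 0.5)
        # independent term-by-term computation
        ce = np.mean([-np.log(preds["class_probs"][i, targets["class_index"][i]])
                      for i in range(B)])
        mse = np.mean([(preds["future"][i, a, j] - targets["future"][i, a, j]) ** 2
                       for i in range(B) for a in range(3) for j in range(NH)])
        mae_terms = []
        for i in range(B):
            for t in range(W):
                for a in range(3):
                    mae_terms.append(abs(preds["recon"][i, t, a]
                                         - targets["recon"][i, t, a]))
        mae = np.mean(mae_terms)
        bce = np.mean([
            -(targets["excessive"][i] * np.log(preds["excessive_prob"][i])
              + (1 - targets["excessive"][i])
              * np.log(1 - preds["excessive_prob"][i]))
            for i in range(B)
        ])
        oracle = w[0] * ce + w[1] * mse + w[2] * mae + w[3] * bce
        assert composite_loss(preds, targets, w) == pytest.approx(oracle,
                                                                  abs=1e-9)

    def test_rejects_negative_weights(self):
        preds, targets = self._exact_case()
        with pytest.raises(ValueError):
            composite_loss(preds, targets, (1, -1, 1, 1))


class TestGradients:
    def test_analytic_gradients_match_numerical(self, tiny_model):
        model, cfg = tiny_model
        rng = np.random.default_rng(1)
        X = rng.random((3, 12, 4))
        targets = {
            "class_index": np.array([0, 2, 3]),
            "future": rng.random((3, 3, 2)),
            "recon": rng.random((3, 12, 3)),
            "excessive": np.array([0.0, 1.0, 0.0]),
        }

        class NoOp:
            def step(self, *a):
                pass

        def loss_of():
            out = model.forward(X)
            preds = {k: out[k] for k in
                     ("class_probs", "future", "recon", "excessive_prob")}
            return composite_loss(preds, targets, cfg.loss_weights)

        model.train_step(X, targets, NoOp())
        import random as pyrandom

        pyrandom.seed(0)
        eps = 1e-6
        for p in model.params():
            flat, g = p.value.reshape(-1), p.grad.reshape(-1)
            for idx in pyrandom.sample(range(flat.size), min(2, flat.size)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_of()
                flat[idx] = orig - eps
                lm = loss_of()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(num) + abs(g[idx]))
                assert abs(num - g[idx]) / denom < 1e-4, p.name


@pytest.fixture(scope="module")
def small_dataset():
    cfg = GeneratorConfig(n_signals=6, duration_s=30.0, seed=5)
    records, _ = generate_dataset(cfg)
    spec = WindowSpec(stride=60)
    return build_windowed_dataset(records, spec)


class TestTraining:
    def _fast_config(self, **kw):
        base = dict(conv_channels=8, dilations=(1, 2), lstm_hidden=8,
                    latent_dim=8, reg_hidden=8, decoder_hidden=8,
                    batch_size=16, max_epochs=1, patience=5, seed=0,
                    val_fraction=0.2)
        base.update(kw)
        return NetConfig(**base)

    def test_single_epoch_smoke(self, small_dataset):
        model, history = train(small_dataset, self._fast_config())
        assert len(history) == 1
        assert np.isfinite(history[0]["train_loss"])
        assert np.isfinite(history[0]["val_loss"])

    def test_same_seed_identical_histories(self, small_dataset):
        cfg = self._fast_config(max_epochs=2)
        _, h1 = train(small_dataset, cfg)
        _, h2 = train(small_dataset, cfg)
        assert h1 == h2

    def test_training_reduces_loss(self, small_dataset):
        cfg = self._fast_config(max_epochs=5)
        _, history = train(small_dataset, cfg)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_autoencoder_improves_with_training(self, small_dataset):
        """Held-out reconstruction error drops after a few epochs of training."""
        ds = small_dataset
        cfg = self._fast_config(max_epochs=5, seed=1,
                                loss_weights=(0.0, 0.0, 1.0, 0.0))
        untrained = RespMotionNet(cfg, ds.window_len, ds.n_channels,
                                  len(ds.horizons))
        hold = ds.inputs[-8:]
        target = ds.recon[-8:]
        before = np.mean(np.abs(untrained.predict(hold)["recon"] - target))
        model, _ = train(ds, cfg)
        after = np.mean(np.abs(model.predict(hold)["recon"] - target))
        assert after < before

    def test_rejects_empty_dataset(self, small_dataset):
        empty = small_dataset.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            train(empty, self._fast_config())


class TestCheckpoint:
    def test_round_trip_bit_exact_inference(self, small_dataset, tmp_path):
        from respmotion.nn import load_checkpoint, save_checkpoint

        ds = small_dataset
        model, _ = train(ds, NetConfig(conv_channels=8, dilations=(1, 2),
                                       lstm_hidden=8, latent_dim=8,
                                       reg_hidden=8, decoder_hidden=8,
                                       batch_size=16, max_epochs=1, seed=0))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        model2 = load_checkpoint(path)
        X = ds.inputs[:10]
        o1, o2 = model.predict(X), model2.predict(X)
        for k in ("class_probs", "future", "recon", "excessive_prob"):
            assert np.array_equal(o1[k], o2[k])
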