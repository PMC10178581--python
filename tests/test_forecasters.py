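"""Windowing, shape contracts, determinism, degenerate-weight
behaviour and compositional consistency of the forecasters."""

import numpy as np
import pytest

import residuecast as rc
from residuecast._nn import decomp_tensor
from residuecast._tensor import Tensor
from residuecast.autoformer import AutoformerNet, ForecastModelConfig, \
    prepare_decoder_input
from residuecast.decomposition import series_decomp
from residuecast.forecasters import make_windows, save_checkpoint, load_checkpoint


class TestMakeWindows:
    def test_shapes_and_columns(self, small_noisy_dataset):
        w = make_windows(small_noisy_dataset, 14, 7, "train")
        assert w.X.ndim == 3 and w.X.shape[1:] == (14, 3)
        assert w.y.shape == (len(w.X), 7)
        assert len(w.scale) == len(w.X)

    def test_train_windows_fully_inside_train_region(self, small_noisy_dataset):
        w = make_windows(small_noisy_dataset, 14, 7, "train")
        train_days = []  # per series, in the same grouping order as make_windows
        for _, grp in small_noisy_dataset.groupby(
                ["pesticide", "temperature_C", "humidity_pct"], sort=False):
            train_days.append(set(grp.loc[grp["split"] == "train", "day"]))
        for sid, origin in zip(w.series_id, w.origin_day):
            window_days = set(range(origin - 13, origin + 8))
            assert window_days <= train_days[sid], "future data leaked into training"

    def test_test_horizon_inside_test_region(self, small_noisy_dataset):
        w = make_windows(small_noisy_dataset, 14, 7, "test")
        test_days = set(small_noisy_dataset.loc[
            small_noisy_dataset["split"] == "test", "day"])
        for origin in w.origin_day:
            assert {origin + j for j in range(1, 8)} <= test_days

    def test_unsplit_dataset_rejected(self, small_noisy_dataset):
        with pytest.raises(ValueError, match="split"):
            make_windows(small_noisy_dataset.drop(columns="split"), 14, 7)

    def test_too_long_window_lists_offending_series(self, small_noisy_dataset):
        with pytest.raises(ValueError, match="dimethoate"):
            make_windows(small_noisy_dataset, 50, 20, "train")

    def test_destandardize_roundtrip(self, small_noisy_dataset):
        w = make_windows(small_noisy_dataset, 14, 7, "train")
        raw = w.y_raw
        assert raw.shape == w.y.shape
        assert np.all(raw >= 0) or np.min(raw) > -1e-6


class TestPrepareDecoderInput:
    CFG = ForecastModelConfig(context_length=10, label_length=5, horizon=3,
                              decomp_kernel=3)

    def test_lengths(self):
        s, t = prepare_decoder_input(np.arange(10.0), self.CFG)
        assert len(s) == len(t) == 5 + 3

    def test_trend_extension_is_context_mean(self):
        ctx = np.arange(10.0)
        _, trend = prepare_decoder_input(ctx, self.CFG)
        assert np.allclose(trend[-3:], ctx.mean())

    def test_constant_context(self):
        s, t = prepare_decoder_input(np.full(10, 4.2), self.CFG)
        assert np.allclose(s[:5], 0) and np.allclose(t, np.r_[np.full(5, 4.2),
                                                              np.full(3, 4.2)])

    def test_label_equals_context_horizon_one(self):
        cfg = ForecastModelConfig(context_length=8, label_length=8, horizon=1,
                                  decomp_kernel=3)
        s, t = prepare_decoder_input(np.arange(8.0), cfg)
        assert len(s) == 9


class TestShapeContracts:
    @pytest.mark.parametrize("context,horizon,layers", [
        (8, 1, 1), (12, 4, 1), (10, 3, 2),
    ])
    def test_autoformer_output_shape(self, context, horizon, layers, rng):
        cfg = ForecastModelConfig(
            context_length=context, label_length=context // 2, horizon=horizon,
            model_width=8, n_heads=2, feedforward_width=16, decomp_kernel=3,
            n_encoder_layers=layers, n_decoder_layers=layers, seed=0)
        net = AutoformerNet(cfg, n_features=3)
        out = net.forward(rng.normal(size=(5, context, 3)))
        assert out.shape == (5, horizon)
        assert np.all(np.isfinite(out.data))

    def test_wrong_context_length_rejected(self, rng):
        cfg = ForecastModelConfig(context_length=8, label_length=4, horizon=2,
                                  model_width=8, decomp_kernel=3)
        net = AutoformerNet(cfg, n_features=3)
        with pytest.raises(ValueError, match="context length"):
            net.forward(rng.normal(size=(2, 9, 3)))

    @pytest.mark.parametrize("name", ["rnn", "lstm", "transformer"])
    def test_baselines_horizon_output(self, name, rng):
        est = rc.build_baseline(name, context_length=10, horizon=4,
                                model_width=8, epochs=1, random_state=0)
        X = rng.normal(size=(12, 10, 3))
        y = rng.normal(size=(12, 4))
        est.fit(X, y)
        assert est.predict(X).shape == (12, 4)

    def test_unknown_baseline_lists_options(self):
        with pytest.raises(ValueError, match="rnn"):
            rc.build_baseline("gru")


class TestDegenerateWeights:
    def test_zero_trend_projections_leave_trend_unchanged(self, rng):
        cfg = ForecastModelConfig(context_length=10, label_length=5, horizon=3,
                                  model_width=8, decomp_kernel=3, dropout=0.0)
        net = AutoformerNet(cfg, n_features=3)
        for layer in net.dec_layers:
            for proj in (layer.proj1, layer.proj2, layer.proj3):
                proj.W.data[:] = 0.0
        x = rng.normal(size=(4, 10, 3))
        seas = np.empty((4, 8))
        trend = np.empty((4, 8))
        for b in range(4):
            seas[b], trend[b] = prepare_decoder_input(x[b, :, 0], cfg)
        enc = net.encode(x, np.random.default_rng(0), False)
        _, trend_out = net.decode(seas, trend, enc, np.random.default_rng(0), False)
        assert np.allclose(trend_out.data[:, :, 0], trend)


class TestDeterminism:
    def test_same_seed_identical_loss_trace(self, noiseless_decay_dataset):
        w = make_windows(noiseless_decay_dataset, 14, 7, "train")
        traces = []
        for _ in range(2):
            est = rc.AutoformerForecaster(epochs=2, model_width=8, n_heads=2,
                                          feedforward_width=16, random_state=9)
            est.fit(w.X[:40], w.y[:40])
            traces.append(est.loss_trace_)
        assert traces[0] == traces[1]

    def test_forecast_twice_identical(self, noiseless_decay_dataset):
        w = make_windows(noiseless_decay_dataset, 14, 7, "train")
        est = rc.AutoformerForecaster(epochs=1, model_width=8,
                                      feedforward_width=16, random_state=0)
        est.fit(w.X[:30], w.y[:30])
        assert np.array_equal(est.predict(w.X[:5]), est.predict(w.X[:5]))


class TestCompositionalConsistency:
    def test_one_layer_encoder_matches_manual_composition(self, rng):
        cfg = ForecastModelConfig(context_length=10, label_length=5, horizon=2,
                                  model_width=8, decomp_kernel=3, dropout=0.0)
        net = AutoformerNet(cfg, n_features=3)
        x = rng.normal(size=(3, 10, 3))
        full = net.encode(x, np.random.default_rng(0), False)
        # manual: embedding + the single layer's own sub-blocks
        h = net.enc_embed(Tensor(x)) + Tensor(net.enc_pos)
        layer = net.enc_layers[0]
        drng = np.random.default_rng(0)
        s1, _ = decomp_tensor(h + layer.autocorr(h, h, h, drng, False), 3)
        s2, _ = decomp_tensor(s1 + layer.ff(s1, drng, False), 3)
        assert np.allclose(full.data, s2.data)

    def test_tensor_decomp_matches_numpy_decomp(self, rng):
        x = rng.normal(size=(2, 15, 4))
        seasonal, trend = decomp_tensor(Tensor(x), 5)
        for b in range(2):
            ref = series_decomp(x[b], 5)
            assert np.allclose(trend.data[b], ref.trend)
            assert np.allclose(seasonal.data[b], ref.seasonal)


class TestTrainingBehaviour:
    def test_constant_series_loss_near_zero(self):
        X = np.zeros((30, 10, 3))
        y = np.zeros((30, 4))
        est = rc.RNNForecaster(context_length=10, horizon=4, model_width=8,
                               epochs=50, learning_rate=1e-2, random_state=0)
        est.fit(X, y)
        assert est.loss_trace_[-1] < 1e-3

    def test_predict_before_fit_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            rc.RNNForecaster().predict(np.zeros((1, 14, 3)))

    def test_naive_repeats_last_value(self):
        X = np.zeros((2, 5, 3))
        X[:, -1, 0] = [3.0, -1.0]
        est = rc.NaiveLastForecaster(context_length=5, horizon=3).fit(X)
        pred = est.predict(X)
        assert np.array_equal(pred, [[3.0] * 3, [-1.0] * 3])


class TestCheckpointRoundTrip:
    def test_predictions_survive_save_load(self, tmp_path, noiseless_decay_dataset):
        w = make_windows(noiseless_decay_dataset, 14, 7, "train")
        est = rc.AutoformerForecaster(epochs=1, model_width=8,
                                      feedforward_width=16, random_state=4)
        est.fit(w.X[:20], w.y[:20])
        path = tmp_path / "model.npz"
        save_checkpoint(est, path)
        restored = load_checkpoint(path)
        assert np.allclose(restored.predict(w.X[:5]), est.predict(w.X[:5]))
        assert restored.get_params() == est.get_params()
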