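"""Fusion, forward contracts, training behaviour, checkpointing, saliency."""

import numpy as np
import pytest

from mechanoecg.errors import ConfigError, InputError
from mechanoecg.evaluation import pcc
from mechanoecg.fusion_model import (EcgRegressor, ModelConfig, TrainConfig,
                                     TrainedModel, fuse_inputs, load_checkpoint,
                                     reconstruct, saliency_map, save_checkpoint,
                                     train)
from mechanoecg.presets import study_model_config, study_train_config
from mechanoecg.types import UniformSeries


class TestFuseInputs:
    def test_column_order_is_pcg_then_scg(self):
        scg = np.array([1.0, 2.0, 3.0, 4.0])
        pcg = np.array([5.0, 6.0, 7.0, 8.0])
        fused = fuse_inputs(scg, pcg)
        assert fused.shape == (4, 2)
        np.testing.assert_array_equal(fused[:, 0], pcg)
        np.testing.assert_array_equal(fused[:, 1], scg)

    def test_scg_only_mask_zeroes_pcg_column(self):
        fused = fuse_inputs(np.ones(4), np.ones(4), mask="scg_only")
        assert np.all(fused[:, 0] == 0.0)
        assert np.all(fused[:, 1] == 1.0)

    def test_pcg_only_mask_zeroes_scg_column(self):
        fused = fuse_inputs(np.ones(4), np.ones(4), mask="pcg_only")
        assert np.all(fused[:, 0] == 1.0)
        assert np.all(fused[:, 1] == 0.0)

    def test_no_mask_is_identity(self):
        rng = np.random.default_rng(0)
        scg, pcg = rng.standard_normal((2, 16))
        fused = fuse_inputs(scg, pcg, mask="none")
        np.testing.assert_array_equal(fused[:, 0], pcg)
        np.testing.assert_array_equal(fused[:, 1], scg)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError, match="mismatch"):
            fuse_inputs(np.ones(4), np.ones(5))


def _tiny_model(window_len=64, fusion="early"):
    cfg = ModelConfig(lstm_hidden=4, d_model=8, n_transformer_layers=1,
                      n_heads=2, ffn_dim=16, decoder_hidden=8,
                      window_len=window_len, fusion=fusion)
    network = EcgRegressor(cfg, np.random.default_rng(0))
    return TrainedModel(config=cfg, train_config=TrainConfig(), network=network)


class TestForwardContract:
    @pytest.mark.parametrize("steps", [16, 33, 64])
    def test_output_length_equals_input_length(self, steps):
        model = _tiny_model()
        out = model.forward(np.zeros((steps, 2)))
        assert out.shape == (steps,)

    def test_per_modality_fusion_also_time_distributed(self):
        model = _tiny_model(fusion="per_modality")
        out = model.forward(np.zeros((3, 40, 2)))
        assert out.shape == (3, 40)

    def test_eval_mode_bitwise_deterministic(self):
        model = _tiny_model()
        rng = np.random.default_rng(1)
        x = rng.standard_normal((48, 2))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_window_longer_than_pe_table_rejected(self):
        model = _tiny_model(window_len=32)
        with pytest.raises(InputError, match="positional"):
            model.forward(np.zeros((64, 2)))

    def test_zero_input_finite_output(self):
        out = _tiny_model().forward(np.zeros((32, 2)))
        assert np.all(np.isfinite(out))

    def test_invalid_head_split_rejected(self):
        with pytest.raises(ConfigError, match="divisible"):
            ModelConfig(d_model=10, n_heads=3)


def test_parameter_count_matches_closed_form():
    """Hand-computed layer-by-layer count for the early-fusion stack."""
    cfg = study_model_config()
    h, d, f, dh = cfg.lstm_hidden, cfg.d_model, cfg.ffn_dim, cfg.decoder_hidden

    def lstm_dir(n_in):
        return n_in * 4 * h + h * 4 * h + 4 * h

    expected = 2 * lstm_dir(2) + 2 * lstm_dir(2 * h)          # 2 BiLSTM layers
    expected += 2 * h * d + d                                  # projection
    per_layer = 4 * (d * d + d)                                # q, k, v, o
    per_layer += d * f + f + f * d + d                         # feed-forward
    per_layer += 2 * (2 * d)                                   # two layer norms
    expected += cfg.n_transformer_layers * per_layer
    expected += d * dh + dh + dh * 1 + 1                       # MLP decoder
    network = EcgRegressor(cfg, np.random.default_rng(0))
    assert network.n_parameters == expected


class TestTraining:
    def test_history_logged_and_best_checkpoint_restored(self, trained_small_model):
        history = trained_small_model.history
        assert len(history) == trained_small_model.train_config.epochs
        assert all(np.isfinite(h["train_mse"]) and np.isfinite(h["val_mse"])
                   for h in history)
        # running best of validation MSE is monotone non-increasing
        best = np.minimum.accumulate([h["val_mse"] for h in history])
        assert np.all(np.diff(best) <= 0)

    def test_record_level_split_no_leakage(self, small_cohort, trained_small_model):
        prov = trained_small_model.provenance
        assert set(prov["train_records"]).isdisjoint(prov["val_records"])
        assert len(prov["train_records"]) + len(prov["val_records"]) == 4

    def test_training_is_seeded_and_reproducible(self, small_cohort):
        _, records = small_cohort
        cfg = study_model_config()
        tcfg = study_train_config(epochs=1, seed=7)
        a = train(records[:2], cfg, tcfg)
        b = train(records[:2], cfg, tcfg)
        assert a.history == b.history

    def test_missing_ecg_rejected(self, small_cohort):
        _, records = small_cohort
        bad = [type(records[0])(scg=records[0].scg, pcg=records[0].pcg,
                                ecg=None, subject_id="x",
                                window_len=records[0].window_len)]
        with pytest.raises(InputError, match="ECG"):
            train(bad, study_model_config(), study_train_config(epochs=1))


class TestReconstruct:
    def test_output_length_truncated_to_whole_windows(self, trained_small_model):
        fs = 250.0
        n = 300 + 250  # 2 windows of 250 + remainder
        rng = np.random.default_rng(0)
        scg = UniformSeries(rng.standard_normal(n), fs=fs)
        pcg = UniformSeries(rng.standard_normal(n), fs=fs)
        out = reconstruct(trained_small_model, scg, pcg)
        assert len(out) == 500
        assert out.fs == fs

    def test_wrong_rate_rejected(self, trained_small_model):
        series = UniformSeries(np.zeros(1000), fs=500.0)
        with pytest.raises(InputError, match="250"):
            reconstruct(trained_small_model, series, series)

    def test_beats_untrained_model_on_held_out_record(self, small_cohort,
                                                      trained_small_model):
        _, records = small_cohort
        held_out = [records[i] for i, sid in enumerate(r.subject_id for r in records)
                    if sid in trained_small_model.provenance["val_records"]]
        record = held_out[0]
        untrained = TrainedModel(config=trained_small_model.config,
                                 train_config=trained_small_model.train_config,
                                 network=EcgRegressor(trained_small_model.config,
                                                      np.random.default_rng(99)))
        from mechanoecg.fusion_model import _standardize_windows
        w = trained_small_model.config.window_len
        nw = record.n_samples // w
        truth = _standardize_windows(
            record.ecg.samples[:nw * w].reshape(nw, w)).reshape(-1)
        trained_pcc = pcc(truth, reconstruct(trained_small_model, record.scg,
                                             record.pcg).samples)
        untrained_pcc = pcc(truth, reconstruct(untrained, record.scg,
                                               record.pcg).samples)
        assert trained_pcc > untrained_pcc


class TestCheckpoint:
    def test_round_trip_preserves_forward_pass(self, tmp_path,
                                               trained_small_model):
        path = tmp_path / "model.npz"
        save_checkpoint(trained_small_model, path)
        loaded = load_checkpoint(path)
        rng = np.random.default_rng(5)
        x = rng.standard_normal((trained_small_model.config.window_len, 2))
        np.testing.assert_array_equal(trained_small_model.forward(x),
                                      loaded.forward(x))
        assert loaded.provenance == trained_small_model.provenance


class TestSaliency:
    def test_saliency_nonnegative_and_input_shaped(self, trained_small_model):
        rng = np.random.default_rng(0)
        fused = rng.standard_normal((trained_small_model.config.window_len, 2))
        sal = saliency_map(trained_small_model, fused)
        assert sal.shape == fused.shape
        assert np.all(sal >= 0.0)

    def test_toy_linear_model_localizes_gradient(self):
        """On a network reduced to (near-)linear behaviour, the gradient of
        one output sample concentrates on temporally relevant inputs; at
        minimum it is nonzero and finite everywhere it should be."""
        model = _tiny_model(window_len=16)
        fused = np.zeros((16, 2))
        sal = saliency_map(model, fused, output_indices=np.array([8]))
        assert sal.shape == (16, 2)
        assert np.all(np.isfinite(sal))
        assert sal.sum() > 0.0
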