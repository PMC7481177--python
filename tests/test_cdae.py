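"""Denoising autoencoder: architecture, corruption batching, training and
encoder extraction."""

import numpy as np
import pytest

from deepbeat import cdae
from deepbeat.types import CANONICAL_NOISE_FACTORS, ValidationError


@pytest.fixture(scope="module")
def toy_windows():
    """A tiny bank of noisy-sinusoid pulse windows for smoke training."""
    rng = np.random.default_rng(0)
    t = np.arange(800) / 32.0
    base = np.stack([np.clip(np.sin(2 * np.pi * f * t), 0, None)
                     for f in rng.uniform(0.9, 2.0, size=64)])
    return base


class TestCorruptBatch:
    def test_zero_factor_returns_clean(self):
        clean = np.random.default_rng(1).random((6, 800))
        corrupted, assigned = cdae.corrupt_batch(clean, factors=[0.0])
        np.testing.assert_array_equal(corrupted, clean)
        np.testing.assert_array_equal(assigned, 0.0)

    def test_canonical_factor_set_round_robin(self):
        clean = np.random.default_rng(2).random((14, 800))
        _, assigned = cdae.corrupt_batch(clean)
        assert sorted(set(assigned)) == sorted(CANONICAL_NOISE_FACTORS)

    def test_per_item_noise_sd_calibrated(self):
        clean = np.random.default_rng(3).normal(size=(21, 800))
        corrupted, assigned = cdae.corrupt_batch(
            clean, rng=np.random.default_rng(4))
        for i in range(len(clean)):
            if assigned[i] < 0.25:
                continue  # sub-sd factors are noisier to estimate
            ratio = (corrupted[i] - clean[i]).std() / (assigned[i] * clean[i].std())
            assert 0.9 <= ratio <= 1.1

    def test_empty_factor_set_rejected(self):
        with pytest.raises(ValidationError):
            cdae.corrupt_batch(np.zeros((2, 800)), factors=[])


class TestArchitecture:
    def test_default_latent_length_is_100(self):
        cfg = cdae.CdaeConfig()
        assert cfg.latent_length == 100
        assert cfg.latent_length < cfg.input_length

    @pytest.mark.parametrize("length,pool", [(800, 2), (810, 3), (64, 2)])
    def test_latent_always_compressed(self, length, pool):
        cfg = cdae.CdaeConfig(input_length=length, pool=pool)
        assert cfg.latent_length < cfg.input_length

    def test_indivisible_input_length_rejected(self):
        with pytest.raises(ValidationError):
            cdae.CdaeConfig(input_length=801, pool=2)

    def test_same_seed_identical_initialization(self):
        a = cdae.build_cdae(cdae.CdaeConfig(seed=5))
        b = cdae.build_cdae(cdae.CdaeConfig(seed=5))
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_reconstruction_shape_contract(self, toy_windows):
        model = cdae.build_cdae(cdae.CdaeConfig(seed=0))
        z = cdae.reconstruct(model, toy_windows[:4])
        assert z.shape == (4, 800)
        assert np.all(np.isfinite(z))
        with pytest.raises(ValidationError):
            cdae.reconstruct(model, np.zeros((2, 700)))

    def test_batch_equals_per_item_reconstruction(self, toy_windows):
        model = cdae.build_cdae(cdae.CdaeConfig(seed=0))
        batch = cdae.reconstruct(model, toy_windows[:6])
        single = np.stack([cdae.reconstruct(model, w) for w in toy_windows[:6]])
        np.testing.assert_allclose(batch, single, atol=1e-6)


class TestTraining:
    def test_identity_reconstruction_mse_is_zero(self, toy_windows):
        assert cdae.mse(toy_windows, toy_windows) == 0.0

    def test_smoke_training_reduces_validation_loss(self, toy_windows):
        cfg = cdae.CdaeConfig(epochs=5, seed=1, batch=16)
        model = cdae.build_cdae(cfg)
        corrupted, _ = cdae.corrupt_batch(toy_windows,
                                          rng=np.random.default_rng(9))
        history = cdae.train_cdae(model, corrupted, toy_windows, cfg)
        assert len(history["train_loss"]) == 5
        assert np.all(np.isfinite(history["train_loss"]))
        assert history["val_loss"][-1] < history["val_loss"][0]

    def test_lr_schedule_decrements_additively_with_floor(self, toy_windows):
        # patience 1 forces decrements whenever validation loss stalls
        cfg = cdae.CdaeConfig(epochs=6, seed=2, batch=16, lr=2e-3,
                              lr_patience=1, lr_decrement=1e-3, lr_floor=1e-5)
        model = cdae.build_cdae(cfg)
        history = cdae.train_cdae(model, toy_windows, toy_windows, cfg)
        lrs = history["lr"]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        assert min(lrs) >= cfg.lr_floor

    def test_shape_mismatch_rejected(self, toy_windows):
        model = cdae.build_cdae(cdae.CdaeConfig(seed=0))
        with pytest.raises(ValidationError):
            cdae.train_cdae(model, toy_windows, toy_windows[:, :400])


class TestEncoderExtraction:
    def test_three_conv_parameter_pairs(self):
        model = cdae.build_cdae(cdae.CdaeConfig(seed=0))
        enc = cdae.extract_encoder(model)
        assert len(enc.weights) == 3 and len(enc.biases) == 3

    def test_save_load_bit_identical(self, tmp_path):
        model = cdae.build_cdae(cdae.CdaeConfig(seed=7))
        enc = cdae.extract_encoder(model)
        enc.save(tmp_path / "enc.npz")
        loaded = cdae.EncoderWeights.load(tmp_path / "enc.npz")
        for a, b in zip(enc.weights + enc.biases,
                        loaded.weights + loaded.biases):
            np.testing.assert_array_equal(a, b)

    def test_extracted_weights_reproduce_encoder_activations(self, toy_windows):
        cfg = cdae.CdaeConfig(seed=3)
        model = cdae.build_cdae(cfg)
        enc = cdae.extract_encoder(model)
        fresh = cdae.build_cdae(cdae.CdaeConfig(seed=99))
        convs = [l for l in fresh.encoder.layers
                 if hasattr(l, "W")]
        for conv, w, b in zip(convs, enc.weights, enc.biases):
            conv.W.value = w.copy()
            conv.b.value = b.copy()
        a = model.encode(toy_windows[:4])
        b = fresh.encode(toy_windows[:4])
        assert np.max(np.abs(a - b)) < 1e-6

    def test_checkpoint_roundtrip(self, tmp_path, toy_windows):
        cfg = cdae.CdaeConfig(seed=4)
        model = cdae.build_cdae(cfg)
        model.save(tmp_path / "cdae.npz")
        loaded = cdae.Cdae.load(tmp_path / "cdae.npz", cfg)
        np.testing.assert_array_equal(
            cdae.reconstruct(model, toy_windows[:2]),
            cdae.reconstruct(loaded, toy_windows[:2]))


class TestDenoisingProperty:
    def test_trained_cdae_beats_identity_at_mid_and_high_noise(
            self, benchmark_data, trained_cdae):
        """The headline property: after training, reconstruction error
        against the clean target is below the corrupted input's error for
        noise factors >= 0.5."""
        model, history = trained_cdae
        assert np.all(np.isfinite(history["train_loss"]))
        assert history["val_loss"][-1] < history["val_loss"][0]
        data = benchmark_data
        # held-out pairs: the benchmark's test records
        import deepbeat.preprocess as prep
        import deepbeat.simulator as sim
        from deepbeat.types import Rhythm, WindowSpec
        config = sim.GenerationConfig(duration=100.0)
        spec = WindowSpec()
        for factor in (0.5, 0.75, 1.0, 2.0, 5.0):
            mses_in, mses_rec = [], []
            for s in range(12):
                rec = sim.simulate_record(
                    Rhythm.AF if s % 2 else Rhythm.SINUS, factor, config,
                    300000 + s)
                wc = prep.window_signal(rec.clean, spec)
                wx = prep.window_signal(rec.corrupted, spec)
                for c, x in zip(wc, wx):
                    z = cdae.reconstruct(model, x.samples)
                    mses_in.append(cdae.mse(x.samples, c.samples))
                    mses_rec.append(cdae.mse(z, c.samples))
            assert np.mean(mses_rec) < np.mean(mses_in), (
                f"no denoising gain at factor {factor}")
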