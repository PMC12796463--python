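import numpy as np
import pytest

from pcvae import (ModelConfig, PCVAEModel, decode, encode, forward,
                   load_checkpoint, reparameterize, save_checkpoint)
from pcvae.nn import autograd as ag
from pcvae.nn.autograd import Tensor


@pytest.fixture
def model(small_model_cfg):
    return PCVAEModel(small_model_cfg, seed=5)


@pytest.fixture
def cloud(rng):
    return (rng.normal(size=(40, 2)) * 0.3).clip(-1, 1)


class TestEncode:
    def test_permutation_invariance_random_weights(self, model, cloud, rng):
        base = encode(model, cloud)
        for _ in range(100):
            perm = rng.permutation(len(cloud))
            code = encode(model, cloud[perm])
            np.testing.assert_allclose(code.mu, base.mu, rtol=1e-5, atol=1e-7)
            np.testing.assert_allclose(code.sigma, base.sigma, rtol=1e-5,
                                       atol=1e-7)

    def test_duplicating_every_point_preserves_mean_pooled_code(self, model,
                                                                cloud):
        base = encode(model, cloud)
        doubled = encode(model, np.vstack([cloud, cloud]))
        np.testing.assert_allclose(doubled.mu, base.mu, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(doubled.sigma, base.sigma, rtol=1e-5,
                                   atol=1e-7)

    def test_zero_network_gives_standard_normal_posterior(self, small_model_cfg,
                                                          cloud):
        from dataclasses import replace

        cfg = replace(small_model_cfg, batchnorm=False)
        model = PCVAEModel(cfg, seed=0)
        for _, p in model.encoder.named_parameters():
            p.data[:] = 0.0
        code = encode(model, cloud)
        np.testing.assert_array_equal(code.mu, 0.0)
        np.testing.assert_array_equal(code.sigma, 1.0)

    def test_wrong_dimension_rejected(self, model, rng):
        with pytest.raises(ValueError, match="expected"):
            encode(model, rng.normal(size=(10, 3)))

    def test_eval_mode_encode_is_deterministic(self, model, cloud):
        a = encode(model, cloud)
        b = encode(model, cloud)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.sigma, b.sigma)


class TestReparameterize:
    def test_zero_eps_returns_mu(self):
        mu = np.array([0.3, -2.0])
        z = reparameterize(mu, np.array([1.0, 2.0]), np.zeros(2))
        np.testing.assert_array_equal(z, mu)

    def test_elementwise_arithmetic(self):
        z = reparameterize(np.array([1.0, 2.0]), np.array([1.0, 1.0]),
                           np.array([0.5, -0.5]))
        np.testing.assert_allclose(z, [1.5, 1.5])

    def test_sample_moments_match_mu_sigma(self, rng):
        mu, sigma = np.array([0.5, -1.0]), np.array([0.7, 1.3])
        n = 100_000
        eps = rng.standard_normal((n, 2))
        z = reparameterize(np.tile(mu, (n, 1)), np.tile(sigma, (n, 1)), eps)
        se_mean = sigma / np.sqrt(n)
        assert np.all(np.abs(z.mean(0) - mu) < 3 * se_mean)
        se_sd = sigma / np.sqrt(2 * (n - 1))
        assert np.all(np.abs(z.std(0, ddof=1) - sigma) < 3 * se_sd)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            reparameterize(np.zeros(2), np.zeros(2), np.zeros(2))


class TestDecode:
    def test_output_shape_is_fixed_reconstruction_size(self, model, rng):
        for _ in range(3):
            z = rng.normal(size=model.config.d)
            out = decode(model, z)
            assert out.shape == (model.config.n_output_points, model.config.p)

    def test_outputs_strictly_inside_unit_interval(self, model, rng):
        z = rng.normal(size=model.config.d) * 3
        out = decode(model, z)
        assert np.all(np.abs(out) < 1.0)

    def test_deterministic_in_eval_mode(self, model, rng):
        z = rng.normal(size=model.config.d)
        np.testing.assert_array_equal(decode(model, z), decode(model, z))

    def test_wrong_latent_length_rejected(self, model):
        with pytest.raises(ValueError):
            decode(model, np.zeros(model.config.d + 1))


class TestForward:
    def test_reproducible_with_fixed_seed(self, model, cloud):
        a = forward(model, cloud, rng=77)
        b = forward(model, cloud, rng=77)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_permutation_changes_nothing_given_same_eps(self, model, cloud,
                                                        rng):
        perm = rng.permutation(len(cloud))
        recon_a, mu_a, sig_a = forward(model, cloud, rng=5)
        recon_b, mu_b, sig_b = forward(model, cloud[perm], rng=5)
        np.testing.assert_allclose(mu_b, mu_a, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(sig_b, sig_a, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(recon_b, recon_a, rtol=1e-4, atol=1e-6)

    def test_reconstruction_size_independent_of_input_size(self, model, rng):
        for n in (3, 40, 500):
            recon, _, _ = forward(model, rng.normal(size=(n, 2)) * 0.2, rng=1)
            assert recon.shape == (model.config.n_output_points, 2)


class TestGradientFlow:
    def test_total_loss_has_finite_nonzero_grads_for_phi_and_theta(
            self, model, rng):
        from pcvae.train import _batch_loss

        model.train()
        batch = (rng.normal(size=(4, 24, 2)) * 0.4).astype(np.float32)
        eps = rng.standard_normal((4, model.config.d))
        total, _, _ = _batch_loss(model, batch, beta=1e-3, eps=eps)
        total.backward()
        enc = [p.grad for _, p in model.encoder.named_parameters()]
        dec = [p.grad for _, p in model.decoder.named_parameters()]
        assert all(g is not None and np.all(np.isfinite(g)) for g in enc + dec)
        assert any(np.abs(g).max() > 0 for g in enc)
        assert any(np.abs(g).max() > 0 for g in dec)


class TestCheckpoint:
    def test_round_trip_preserves_encoding_and_decoding(self, model, cloud,
                                                        tmp_path, rng):
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        a, b = encode(model, cloud), encode(loaded, cloud)
        np.testing.assert_array_equal(a.mu, b.mu)
        z = rng.normal(size=model.config.d)
        np.testing.assert_array_equal(decode(model, z), decode(loaded, z))

    def test_config_is_echoed(self, model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        assert load_checkpoint(path).config == model.config


class TestConfigValidation:
    def test_heads_must_divide_channels(self):
        with pytest.raises(ValueError, match="heads"):
            ModelConfig(decoder_fc_widths=(16, 32, 65), n_attention_heads=4)

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(p=4)
        with pytest.raises(ValueError):
            ModelConfig(d=0)
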