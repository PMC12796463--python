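import numpy as np
import pytest

from pcvae import (HeterogeneitySpec, ModelConfig, Particle, ParticleDataset,
                   TrainConfig, normalize_dataset, simulate_preset, train,
                   uniform)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_model_cfg():
    """Scaled-down architecture for fast unit tests of model mechanics."""
    return ModelConfig(p=2, d=4, encoder_widths=(8, 16, 32),
                       decoder_fc_widths=(16, 32, 64), n_attention_heads=4,
                       n_output_points=24, index_embed_dim=4)


@pytest.fixture
def ring_particle(rng):
    """One noisy 8-site ring particle, centered."""
    ang = 2 * np.pi * np.arange(8) / 8
    sites = 55.0 * np.column_stack([np.cos(ang), np.sin(ang)])
    pts = np.repeat(sites, 20, axis=0) + rng.normal(0, 3, (160, 2))
    return Particle(points=pts - pts.mean(axis=0), id="ring")


@pytest.fixture
def tiny_dataset(rng):
    particles = [
        Particle(points=rng.normal(scale=30.0, size=(rng.integers(5, 40), 2)),
                 id=i)
        for i in range(10)
    ]
    return ParticleDataset(particles=particles)


# -- shared end-to-end training runs (expensive; computed once per session) ---

@pytest.fixture(scope="session")
def npc2d_run():
    """Default-config training on the heterogeneous 2D ring dataset.

    400 particles, radius ~ U(45, 65) nm, ~150 localizations per particle,
    3 nm localization noise, d=8, M=8, 4 epochs. Shared by the end-to-end
    recovery, training-progress and robustness tests.
    """
    from pcvae import encode_dataset

    dataset, truth = simulate_preset(
        "npc2d", seed=11, n_particles=400,
        het=HeterogeneitySpec(radius=uniform(45.0, 65.0)))
    norm = normalize_dataset(dataset)
    model, history = train(norm, ModelConfig(p=2), TrainConfig(seed=11))
    mu, sigma = encode_dataset(model, norm)
    return {"dataset": dataset, "normalized": norm, "truth": truth,
            "model": model, "history": history, "mu": mu, "sigma": sigma}


@pytest.fixture(scope="session")
def tetra3d_run():
    """Default-config training on the heterogeneous tetrahedron dataset.

    220 particles, height ~ U(45, 95) nm, PAINT-like high localization counts.
    """
    from pcvae import encode_dataset

    dataset, truth = simulate_preset("tetra3d", seed=7, n_particles=220)
    norm = normalize_dataset(dataset)
    model, history = train(norm, ModelConfig(p=3), TrainConfig(seed=7))
    mu, sigma = encode_dataset(model, norm)
    return {"dataset": dataset, "normalized": norm, "truth": truth,
            "model": model, "history": history, "mu": mu, "sigma": sigma}
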