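"""Train the PC-VAE on synthetic rings and find the radius-encoding latent.

Simulates 400 ring particles with radius ~ U(45, 65) nm, trains the
variational autoencoder with the default configuration (d=8, batch size 8,
4 epochs, Adam 1e-4), encodes every particle, and reports the Pearson and
Spearman correlation of each latent dimension with the true radius.
Takes a couple of minutes on one CPU core.
"""

from pcvae import (HeterogeneitySpec, ModelConfig, TrainConfig, correlate,
                   encode_dataset, normalize_dataset, simulate_preset, train,
                   uniform)

dataset, truth = simulate_preset(
    "npc2d", seed=11, n_particles=400,
    het=HeterogeneitySpec(radius=uniform(45.0, 65.0)))
norm = normalize_dataset(dataset)

model, history = train(norm, ModelConfig(p=2), TrainConfig(seed=11))
frame = history.to_frame()
k = len(frame) // 10
print(f"trained {len(frame)} steps; Chamfer term "
      f"{frame.loss_chamfer.head(k).mean():.3f} -> "
      f"{frame.loss_chamfer.tail(k).mean():.3f} (first/last 10% of steps)")

mu, sigma = encode_dataset(model, norm)
report = correlate(mu, truth.true_radius_nm.to_numpy())
print(report.to_frame().round(3).to_string(index=False))
best = report.best_dim()
print(f"best latent dimension: {best} with |Spearman| = "
      f"{abs(report.spearman[best]):.3f}")
# Particles ordered along that dimension are ordered by ring radius; the
# remaining dimensions mostly carry localization-count and residual modes.
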