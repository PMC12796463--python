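# pcvae — continuous structural heterogeneity in SMLM point clouds

Single-molecule localization microscopy (SMLM) images a macromolecular
structure as a list of emitter coordinates rather than pixels. Fusing many
segmented copies ("particles") into one high signal-to-noise reconstruction
assumes the copies are identical — but nuclear pore complexes vary in ring
radius and inter-ring distance, DNA-origami tetrahedra in height. `pcvae`
detects such *continuous* modes of variation directly on 2D/3D localization
point clouds with a point-cloud variational autoencoder, for microscopists
and method developers who need template-free heterogeneity analysis that
scales linearly with the number of particles.

## Method in brief

A particle with N localizations is a matrix **X** ∈ R^(N×p), p ∈ {2, 3}.
A permutation-invariant encoder (shared-weight per-point MLPs 64→128→1024
with batch norm + ReLU, mean pooling, two MLP heads) produces a diagonal
Gaussian posterior q_φ(z|X) = N(μ, diag σ²) in R^8; the reparameterization
z = μ + σ⊙ε keeps sampling differentiable. A decoder (FC 256→512→1024 with
Tanh + batch norm, a linear skip from z, two 1024-channel pointwise
convolutions, 4-head self-attention, Tanh output) generates a fixed-size
point cloud X̂ ∈ (−1, 1)^(N_s×p). Training minimizes

    L = (1/N)[ Σ_{x∈X} min_{x̂∈X̂} ‖x−x̂‖² + Σ_{x̂∈X̂} min_{x∈X} ‖x−x̂‖² ]
        + β(t) · ½ Σ_i (μ_i² + σ_i² − log σ_i² − 1)

with Adam (lr 1e-4, weight decay 1e-5), mini-batches of M = 8 particles,
4 epochs, and a sigmoid warm-up of β over the first 5000 steps. After
training, each particle's latent mean μ orders the dataset along every
latent dimension; 20 equal-count bins per dimension are fused into
super-particles, and model-based radius/height estimators validate which
dimension encodes which geometric mode. A synthetic SMLM simulator
(8-site rings, 32-site double rings, 4-site tetrahedra, stochastic labeling,
zero-truncated Poisson localization counts, Gaussian localization noise)
provides ground truth for all of it.

The network runs on a small numpy autodiff engine bundled with the package
(`pcvae.nn`) — no deep-learning framework required; a full training run takes
a few minutes on one CPU core.

## Worked example

`examples/02_train_and_correlate.py` simulates 400 heterogeneous 2D ring
particles (radius ~ U(45, 65) nm, ≈150 localizations each, 3 nm precision),
trains with the default configuration and correlates every latent dimension
with the true radius:

```
trained 200 steps; Chamfer term 0.826 -> 0.166 (first/last 10% of steps)
 latent_dim  pearson_r  spearman_rho  defined
          0      0.536         0.647     True
          1     -0.627        -0.708     True
          2      0.031         0.048     True
          3     -0.323        -0.407     True
          4      0.004         0.001     True
          5      0.363         0.369     True
          6     -0.284        -0.344     True
          7      0.580         0.571     True
best latent dimension: 1 with |Spearman| = 0.708
```

The falling Chamfer term shows the reconstructions converging; latent
dimension 1 rank-correlates with the true ring radius at |ρ| ≈ 0.71, so
ordering particles along it orders them by radius. Several other dimensions
carry partial radius and localization-count information — disentanglement
across latent units is not enforced, and how much of one mode concentrates
in a single dimension varies between training runs (see
`docs/methods.md` for the honest margins). `examples/03_bin_and_superparticles.py`
continues into binning and super-particle fusion;
`examples/01_simulate_and_estimate.py` exercises the simulator and the
geometric estimators alone.

## Command line

Every stage is also a `pcvae` subcommand operating on plain CSV/HDF5
localization tables (`particle_id, x_nm, y_nm[, z_nm]`):

```bash
pcvae simulate --preset npc2d --n-particles 400 --seed 11 \
      --out locs.csv --ground-truth truth.csv
pcvae train --data locs.csv --seed 11 --out-checkpoint model.npz \
      --history-csv history.csv
pcvae analyze --checkpoint model.npz --data locs.csv \
      --parameter-csv truth.csv --out-dir analysis/
pcvae estimate --data locs.csv --model npc2d --out estimates.csv
pcvae robustness --data locs.csv --parameter-csv truth.csv \
      --ratios 1.0,0.5 --seed 11 --out robustness.csv
pcvae run --config config.yaml --seed 11   # chain stages + manifest
```

`pcvae run` writes all stage outputs and a manifest (config echo, seeds,
version, per-stage wall time) into one run directory; any YAML config is
merged over the documented defaults.

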