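"""Mini-batch training loop and whole-dataset latent encoding.

Training follows the stochastic mini-batch scheme: per epoch the particles are
shuffled (seeded), split into batches of M (the last, smaller batch is kept),
every particle is resampled with replacement to the fixed point count N_s so a
batch is one dense array, and Adam updates the parameters of the encoder and
decoder against the Chamfer + beta(step) * KLD objective. Inference encodes
each particle from *all* of its localizations (no resampling) in evaluation
mode and reports the posterior mean as the particle's latent coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ParticleDataset, resample_particle
from .losses import LossConfig, beta_schedule
from .model import ModelConfig, PCVAEModel
from .nn import Adam
from .nn import autograd as ag
from .nn.autograd import Tensor


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimization."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam, lr 1e-4, weight decay 1e-5, M=8,
    4 epochs, KLD warm-up per :class:`LossConfig`)."""

    batch_size: int = 8
    epochs: int = 4
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs >= 1 and learning_rate > 0 "
                             "required")


@dataclass
class TrainHistory:
    """One record per optimization step."""

    step: list[int] = field(default_factory=list)
    epoch: list[int] = field(default_factory=list)
    loss_total: list[float] = field(default_factory=list)
    loss_chamfer: list[float] = field(default_factory=list)
    loss_kld: list[float] = field(default_factory=list)
    beta: list[float] = field(default_factory=list)

    def append(self, step, epoch, total, chamfer, kld, beta):
        self.step.append(step)
        self.epoch.append(epoch)
        self.loss_total.append(total)
        self.loss_chamfer.append(chamfer)
        self.loss_kld.append(kld)
        self.beta.append(beta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": self.step, "epoch": self.epoch,
            "loss_total": self.loss_total, "loss_chamfer": self.loss_chamfer,
            "loss_kld": self.loss_kld, "beta": self.beta,
        })


def _batch_loss(model: PCVAEModel, batch: np.ndarray, beta: float,
                eps: np.ndarray, targets: list[np.ndarray] | None = None,
                ) -> tuple[Tensor, float, float]:
    """Graph for the mean per-particle loss of one (B, N_s, p) batch.

    ``targets`` optionally overrides the Chamfer reference sets (one per
    particle); by default the encoder inputs — the resampled point sets —
    serve as their own reconstruction targets.
    """
    x = Tensor(batch)
    mu, logvar = model.encoder.forward_batch(x)
    sigma = ag.exp(ag.mul(logvar, 0.5))
    z = ag.add(mu, ag.mul(sigma, Tensor(eps.astype(np.float32))))
    recon = model.decoder.forward_batch(z)

    b = batch.shape[0]
    if targets is None:
        targets = [batch[i] for i in range(b)]
    chamfer_terms = [ag.chamfer_to_fixed(targets[i], ag.take_row(recon, i))
                     for i in range(b)]
    chamfer_sum = chamfer_terms[0]
    for term in chamfer_terms[1:]:
        chamfer_sum = ag.add(chamfer_sum, term)
    chamfer_mean = ag.mul(chamfer_sum, 1.0 / b)

    # KLD per particle: 1/2 sum_i (mu^2 + sigma^2 - log sigma^2 - 1)
    kld_per = ag.mul(
        ag.tsum(ag.add(ag.add(ag.mul(mu, mu), ag.exp(logvar)),
                       ag.add(ag.neg(logvar), -1.0)), axis=1),
        0.5)
    kld_mean = ag.tmean(kld_per)

    total = ag.add(chamfer_mean, ag.mul(kld_mean, beta))
    return total, float(chamfer_mean.data), float(kld_mean.data)


def train(dataset: ParticleDataset, model_cfg: ModelConfig,
          train_cfg: TrainConfig, n_resample_points: int | None = None,
          ) -> tuple[PCVAEModel, TrainHistory]:
    """Train a fresh PC-VAE on a normalized dataset.

    ``n_resample_points`` is the per-particle point count used for batching;
    it defaults to the model's reconstruction size N_s.
    """
    if not dataset.normalized:
        raise ValueError("dataset must be normalized before training")
    if len(dataset) < train_cfg.batch_size:
        raise ValueError(
            f"need at least batch_size={train_cfg.batch_size} particles, "
            f"got {len(dataset)}")
    if dataset.p != model_cfg.p:
        raise ValueError(f"dataset p={dataset.p} != model p={model_cfg.p}")

    ns = n_resample_points or model_cfg.n_output_points
    root = np.random.SeedSequence(train_cfg.seed)
    init_seed, loop_seed = root.spawn(2)
    model = PCVAEModel(model_cfg, seed=init_seed.generate_state(1)[0] % (2**31))
    model.train()
    rng = np.random.default_rng(loop_seed)
    optimizer = Adam(model.parameters(), lr=train_cfg.learning_rate,
                     weight_decay=train_cfg.weight_decay)
    history = TrainHistory()
    n = len(dataset)
    m = train_cfg.batch_size
    step = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, m):
            idx = order[start:start + m]
            batch = np.stack([
                resample_particle(dataset[i], ns, rng).points
                for i in idx]).astype(np.float32)
            beta = beta_schedule(step, train_cfg.loss)
            eps = rng.standard_normal((len(idx), model_cfg.d))
            optimizer.zero_grad()
            total, chamfer_val, kld_val = _batch_loss(model, batch, beta, eps)
            if not np.isfinite(total.data):
                raise TrainingDivergedError(
                    f"non-finite loss at optimization step {step}")
            total.backward()
            optimizer.step()
            history.append(step, epoch, float(total.data), chamfer_val,
                           kld_val, beta)
            step += 1
    model.eval()
    return model, history


def encode_dataset(model: PCVAEModel,
                   dataset: ParticleDataset) -> tuple[np.ndarray, np.ndarray]:
    """Encode every particle from all its localizations.

    Returns the (n_particles, d) matrices of posterior means and standard
    deviations. Evaluation mode (frozen batch statistics) makes the result
    deterministic.
    """
    if dataset.p != model.config.p:
        raise ValueError(f"dataset p={dataset.p} != model p={model.config.p}")
    was_training = model.training
    model.eval()
    mus, sigmas = [], []
    try:
        with ag.no_grad():
            # chunk by particles to bound the peak footprint of the 1024-wide
            # per-point feature arrays
            max_points = 50_000
            start = 0
            while start < len(dataset):
                stop = start
                total = 0
                while stop < len(dataset) and (total == 0
                                               or total + dataset[stop].n_points
                                               <= max_points):
                    total += dataset[stop].n_points
                    stop += 1
                chunk = dataset.particles[start:stop]
                flat = np.concatenate([p.points for p in chunk]).astype(
                    np.float32)
                lengths = np.array([p.n_points for p in chunk])
                mu, logvar = model.encoder.forward_ragged(Tensor(flat), lengths)
                mus.append(np.asarray(mu.data, dtype=np.float64))
                sigmas.append(np.exp(0.5 * np.asarray(logvar.data,
                                                      dtype=np.float64)))
                start = stop
    finally:
        if was_training:
            model.train()
    return np.concatenate(mus), np.concatenate(sigmas)
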