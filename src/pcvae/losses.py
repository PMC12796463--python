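"""Reconstruction, regularization and scheduled total loss of the PC-VAE.

The reconstruction term is the symmetric Chamfer distance

    L_recon = (1/N) [ sum_x min_xhat ||x - xhat||^2 + sum_xhat min_x ||x - xhat||^2 ]

with N the size of the *input* set (both sums share that normalizer, also
when the reconstruction has a different point count). The regularizer is the
closed-form KL divergence of a diagonal Gaussian posterior against the
standard-normal prior,

    L_KLD = 1/2 sum_i (mu_i^2 + sigma_i^2 - log sigma_i^2 - 1),

and the total loss is L_recon + beta(step) * L_KLD with a sigmoid warm-up of
beta over the first ``warmup_steps`` optimization steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class LossConfig:
    """beta ceiling and KLD warm-up length (in optimization steps)."""

    beta_max: float = 1e-3
    warmup_steps: int = 5000

    def __post_init__(self):
        if self.beta_max < 0:
            raise ValueError("beta_max must be nonnegative")
        if self.warmup_steps < 0:
            raise ValueError("warmup_steps must be nonnegative")


def chamfer(x: np.ndarray, xhat: np.ndarray) -> float:
    """Symmetric Chamfer distance between two point sets, normalized by |x|."""
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.ndim != 2 or xhat.ndim != 2:
        raise ValueError("point sets must be 2-D arrays")
    if x.shape[0] == 0 or xhat.shape[0] == 0:
        raise ValueError("point sets must be non-empty")
    if x.shape[1] != xhat.shape[1]:
        raise ValueError("point sets must share their spatial dimension")
    d2 = cdist(x, xhat, metric="sqeuclidean")
    return float((d2.min(axis=1).sum() + d2.min(axis=0).sum()) / x.shape[0])


def kld(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL( N(mu, diag(sigma^2)) || N(0, I) ), closed form."""
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if mu.shape != sigma.shape:
        raise ValueError("mu and sigma must have the same shape")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    s2 = sigma**2
    return float(0.5 * np.sum(mu**2 + s2 - np.log(s2) - 1.0))


def beta_schedule(step: int, cfg: LossConfig) -> float:
    """Sigmoid warm-up of beta: ~0 at step 0, beta_max/2 at the midpoint,
    clamped to beta_max from ``warmup_steps`` onward."""
    if cfg.warmup_steps == 0 or step >= cfg.warmup_steps:
        return cfg.beta_max
    k = 12.0
    t = k * (step - cfg.warmup_steps / 2.0) / cfg.warmup_steps
    return cfg.beta_max / (1.0 + np.exp(-t))


def total_loss(x: np.ndarray, xhat: np.ndarray, mu: np.ndarray,
               sigma: np.ndarray, step: int, cfg: LossConfig) -> float:
    """Per-particle total loss: Chamfer + beta(step) * KLD."""
    return chamfer(x, xhat) + beta_schedule(step, cfg) * kld(mu, sigma)
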