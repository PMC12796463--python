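"""Latent-space heterogeneity analysis.

After training, particles are ordered along each latent dimension, split into
equal-count bins, and the particles of each bin are registered and merged into
a *super-particle* whose high signal-to-noise ratio makes the structural state
of that bin visible. Latent coordinates are validated against independent
per-particle parameter estimates through Pearson and Spearman correlations,
and the subsampling experiment measures how those correlations degrade when
localizations are randomly discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr, spearmanr

from .io import Particle, ParticleDataset, normalize_dataset, subsample_particle
from .model import ModelConfig, PCVAEModel
from .train import TrainConfig, encode_dataset, train


@dataclass(frozen=True)
class BinAssignment:
    """Particles ordered along one latent dimension, cut into equal chunks.

    Chunk size is ceil(n / n_bins); the final bin takes the remainder (e.g.
    218 particles in 20 bins -> 19 bins of 11 and one of 9).
    """

    latent_dim: int
    order: np.ndarray            # particle indices, nondecreasing latent value
    bins: list[np.ndarray]       # consecutive chunks of `order`

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def bin_sizes(self) -> list[int]:
        return [len(b) for b in self.bins]


@dataclass(frozen=True)
class SuperParticle:
    """Registered union point cloud of one bin."""

    points: np.ndarray
    bin_index: int
    member_count: int


def order_and_bin(latents: np.ndarray, dim: int, n_bins: int = 20) -> BinAssignment:
    """Stable-sort particles by one latent coordinate and cut into bins."""
    latents = np.asarray(latents)
    n = latents.shape[0]
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} particles, got {n}")
    order = np.argsort(latents[:, dim], kind="stable")
    size = math.ceil(n / n_bins)
    bins = [order[i:i + size] for i in range(0, n, size)]
    return BinAssignment(latent_dim=dim, order=order, bins=bins)


def _sym_chamfer(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean squared nearest-neighbour distance (registration cost)."""
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, _ = tb.query(a, k=1)
    d_ba, _ = ta.query(b, k=1)
    return float((d_ab**2).mean() + (d_ba**2).mean())


def _rotate_z(points: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    out = points.copy()
    out[:, 0] = c * points[:, 0] - s * points[:, 1]
    out[:, 1] = s * points[:, 0] + c * points[:, 1]
    return out


def _golden_section(f, lo: float, hi: float, tol: float = 1e-4) -> float:
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def register_bin(particles: list[Particle], mode: str = "rot_z",
                 grid_deg: float = 2.0) -> SuperParticle:
    """Merge one bin's particles into a super-particle.

    The first particle is the reference; each subsequent particle is rotated
    about z by the angle minimizing the symmetric Chamfer cost against the
    growing merged cloud (coarse grid search at ``grid_deg`` resolution, then
    golden-section refinement around the best grid angle). ``mode='none'``
    skips registration and returns the plain union. Structures treated here
    have a symmetry/optical axis along z, so in-plane rotation is the only
    free alignment parameter once particles are centered.
    """
    if not particles:
        raise ValueError("empty bin")
    if mode not in ("rot_z", "none"):
        raise ValueError(f"unknown registration mode {mode!r}")
    if mode == "none" or len(particles) == 1:
        merged = np.vstack([p.points for p in particles])
        return SuperParticle(points=merged, bin_index=-1,
                             member_count=len(particles))
    merged = particles[0].points.copy()
    step = np.deg2rad(grid_deg)
    grid = np.arange(0.0, 2 * np.pi, step)
    for particle in particles[1:]:
        pts = particle.points
        costs = [_sym_chamfer(_rotate_z(pts, t), merged) for t in grid]
        best = int(np.argmin(costs))
        theta = _golden_section(
            lambda t: _sym_chamfer(_rotate_z(pts, t), merged),
            grid[best] - step, grid[best] + step)
        candidates = [(costs[0], 0.0), (costs[best], grid[best]),
                      (_sym_chamfer(_rotate_z(pts, theta), merged), theta)]
        _, theta = min(candidates, key=lambda c: c[0])
        merged = np.vstack([merged, _rotate_z(pts, theta)])
    return SuperParticle(points=merged, bin_index=-1,
                         member_count=len(particles))


@dataclass(frozen=True)
class CorrelationReport:
    """Per-latent-dimension Pearson r and Spearman rho against one parameter."""

    pearson: np.ndarray
    spearman: np.ndarray
    defined: np.ndarray  # False where either variable has zero variance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "latent_dim": np.arange(len(self.pearson)),
            "pearson_r": self.pearson,
            "spearman_rho": self.spearman,
            "defined": self.defined,
        })

    def best_dim(self, kind: str = "spearman") -> int:
        values = self.spearman if kind == "spearman" else self.pearson
        masked = np.where(self.defined, np.abs(values), -np.inf)
        return int(np.argmax(masked))

    def max_abs(self, kind: str = "spearman") -> float:
        values = self.spearman if kind == "spearman" else self.pearson
        return float(np.nanmax(np.where(self.defined, np.abs(values), np.nan)))


def correlate(latents: np.ndarray, parameter: np.ndarray) -> CorrelationReport:
    """Pearson and Spearman (average-rank ties) per latent dimension."""
    latents = np.asarray(latents, dtype=np.float64)
    parameter = np.asarray(parameter, dtype=np.float64)
    if latents.ndim != 2 or parameter.shape != (latents.shape[0],):
        raise ValueError("latents must be (n, d) and parameter length n")
    n, d = latents.shape
    if n < 3:
        raise ValueError("need at least 3 particles to correlate")
    pear = np.full(d, np.nan)
    spear = np.full(d, np.nan)
    defined = np.zeros(d, dtype=bool)
    param_const = np.ptp(parameter) == 0
    for j in range(d):
        col = latents[:, j]
        if param_const or np.ptp(col) == 0:
            continue
        pear[j] = pearsonr(col, parameter).statistic
        spear[j] = spearmanr(col, parameter).statistic
        defined[j] = True
    return CorrelationReport(pearson=pear, spearman=spear, defined=defined)


def subsample_dataset(dataset: ParticleDataset, ratio: float,
                      seed: int | np.random.Generator) -> ParticleDataset:
    """Keep floor(ratio * N) localizations per particle (seeded, without
    replacement). ratio = 1.0 returns the dataset unchanged."""
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    if ratio == 1.0:
        return dataset
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    particles = [subsample_particle(p, ratio, rng) for p in dataset]
    return replace(dataset, particles=particles)


def robustness_curve(dataset: ParticleDataset, ratios, model_cfg: ModelConfig,
                     train_cfg: TrainConfig, reference_parameter,
                     subsample_seed: int = 0) -> pd.DataFrame:
    """Latent-parameter correlation versus localization sample ratio.

    For each ratio the raw (nm) dataset is subsampled per particle, normalized,
    a fresh model is trained with identical settings, the particles are
    encoded, and |r|, |rho| per latent dimension against the reference
    parameter are recorded. ratio 1.0 reproduces the unsubsampled run for the
    same training seed.
    """
    ratios = list(ratios)
    if any(not (0.0 < r <= 1.0) for r in ratios):
        raise ValueError("ratios must lie in (0, 1]")
    if dataset.normalized:
        raise ValueError("pass the raw (nm) dataset; normalization is redone "
                         "per subsampled dataset")
    reference_parameter = np.asarray(reference_parameter, dtype=np.float64)
    rows = []
    for ratio in ratios:
        sub = normalize_dataset(subsample_dataset(dataset, ratio,
                                                  seed=subsample_seed))
        model, _ = train(sub, model_cfg, train_cfg)
        mu, _ = encode_dataset(model, sub)
        report = correlate(mu, reference_parameter)
        for j in range(model_cfg.d):
            rows.append({
                "ratio": ratio, "latent_dim": j,
                "abs_pearson": abs(report.pearson[j]),
                "abs_spearman": abs(report.spearman[j]),
                "defined": bool(report.defined[j]),
            })
    return pd.DataFrame(rows)
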