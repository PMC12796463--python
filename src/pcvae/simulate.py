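"""Synthetic SMLM particle generator with known ground-truth shape parameters.

Each particle is built from a geometric scaffold of fluorophore binding sites:

* ``ring2d`` — 8 sites on a circle (2D nuclear-pore-complex projection),
* ``double_ring3d`` — two rings of 16 sites separated along z, the second ring
  rotated by half the site spacing (3D NPC),
* ``tetrahedron3d`` — 3 base sites at z = 0 and one apex at z = height
  (DNA-origami tetrahedron).

Sites are stochastically labeled (Bernoulli with probability DOL), each
labeled site emits a Poisson-distributed number of localizations conditioned
on at least one event, localizations get isotropic Gaussian noise, and the
whole particle receives a random rotation about the optical (z) axis.
Per-particle shape parameters (radius, height) are drawn from configurable
distributions so the dataset carries continuous structural heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Particle, ParticleDataset

STRUCTURE_KINDS = ("ring2d", "double_ring3d", "tetrahedron3d")


class DegenerateParticleError(RuntimeError):
    """No binding site got labeled after the maximum number of redraws."""


@dataclass(frozen=True)
class StructureModel:
    """Binding-site scaffold: kind, site count, nominal geometry in nm."""

    kind: str
    radius_nm: float = 55.0
    height_nm: float = 0.0   # ring separation (double_ring3d) or apex height
    base_edge_nm: float = 100.0  # tetrahedron base edge length

    def __post_init__(self):
        if self.kind not in STRUCTURE_KINDS:
            raise ValueError(f"unknown structure kind {self.kind!r}")

    @property
    def n_sites(self) -> int:
        return {"ring2d": 8, "double_ring3d": 32, "tetrahedron3d": 4}[self.kind]

    @property
    def p(self) -> int:
        return 2 if self.kind == "ring2d" else 3

    def site_positions(self, radius_nm: float | None = None,
                       height_nm: float | None = None) -> np.ndarray:
        """Binding-site coordinates, centered at the scaffold centroid."""
        r = self.radius_nm if radius_nm is None else radius_nm
        h = self.height_nm if height_nm is None else height_nm
        if self.kind == "ring2d":
            ang = 2 * np.pi * np.arange(8) / 8
            sites = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        elif self.kind == "double_ring3d":
            ang = 2 * np.pi * np.arange(16) / 16
            lower = np.column_stack([r * np.cos(ang), r * np.sin(ang),
                                     np.full(16, -h / 2)])
            # upper ring offset by half the angular site spacing
            ang2 = ang + np.pi / 16
            upper = np.column_stack([r * np.cos(ang2), r * np.sin(ang2),
                                     np.full(16, h / 2)])
            sites = np.vstack([lower, upper])
        else:  # tetrahedron3d
            circum = self.base_edge_nm / np.sqrt(3.0)
            ang = 2 * np.pi * np.arange(3) / 3
            base = np.column_stack([circum * np.cos(ang), circum * np.sin(ang),
                                    np.zeros(3)])
            apex = np.array([[0.0, 0.0, h]])
            sites = np.vstack([base, apex])
        return sites - sites.mean(axis=0)


@dataclass(frozen=True)
class PhotophysicsSpec:
    """Labeling and localization statistics.

    dol : degree of labeling, the probability a binding site carries a
        fluorophore.
    mean_locs_per_site : Poisson mean of the localization count of a labeled
        site (conditioned on >= 1 event).
    loc_precision_nm : per-axis sigma of the isotropic Gaussian localization
        noise.
    """

    dol: float = 1.0
    mean_locs_per_site: float = 20.0
    loc_precision_nm: float = 3.0

    def __post_init__(self):
        if not (0.0 < self.dol <= 1.0):
            raise ValueError("dol must be in (0, 1]")
        if self.mean_locs_per_site <= 0:
            raise ValueError("mean_locs_per_site must be positive")
        if self.loc_precision_nm < 0:
            raise ValueError("loc_precision_nm must be nonnegative")

    @property
    def expected_locs_per_site(self) -> float:
        """E[count] of the zero-truncated Poisson law."""
        lam = self.mean_locs_per_site
        return lam / (1.0 - np.exp(-lam))


@dataclass(frozen=True)
class Distribution:
    """Scalar sampling law for a shape parameter: fixed, uniform or normal."""

    kind: str               # {"fixed", "uniform", "normal"}
    a: float = 0.0          # value | lower bound | mean
    b: float = 0.0          # unused | upper bound | standard deviation

    def __post_init__(self):
        if self.kind not in ("fixed", "uniform", "normal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "uniform" and not self.b > self.a:
            raise ValueError("uniform distribution needs b > a")
        if self.kind == "normal" and self.b < 0:
            raise ValueError("normal distribution needs sd >= 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return self.a
        if self.kind == "uniform":
            return float(rng.uniform(self.a, self.b))
        return float(rng.normal(self.a, self.b))

    @property
    def mean(self) -> float:
        return 0.5 * (self.a + self.b) if self.kind == "uniform" else self.a


def fixed(v: float) -> Distribution:
    return Distribution("fixed", v)


def uniform(lo: float, hi: float) -> Distribution:
    return Distribution("uniform", lo, hi)


def normal(mean: float, sd: float) -> Distribution:
    return Distribution("normal", mean, sd)


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Per-particle distributions of the scaffold shape parameters."""

    radius: Distribution | None = None
    height: Distribution | None = None


def _zero_truncated_poisson(lam: float, size: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1, by inverse CDF on the shifted law."""
    # P(X >= 1) = 1 - exp(-lam); draw u in (exp(-lam), 1] and invert
    u = rng.uniform(np.exp(-lam), 1.0, size=size)
    from scipy.stats import poisson

    return np.maximum(poisson.ppf(u, lam).astype(np.int64), 1)


def _rot_z(theta: float, p: int) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    if p == 2:
        return np.array([[c, -s], [s, c]])
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def simulate_particle(model: StructureModel, phys: PhotophysicsSpec,
                      rng: np.random.Generator,
                      radius_nm: float | None = None,
                      height_nm: float | None = None,
                      particle_id=None,
                      max_redraws: int = 100) -> tuple[Particle, dict]:
    """Generate one particle; returns the particle and its ground-truth record.

    Labeling is redrawn (up to ``max_redraws`` times) if no site is labeled so
    the requested dataset size is always met exactly.
    """
    sites = model.site_positions(radius_nm=radius_nm, height_nm=height_nm)
    n_sites = sites.shape[0]
    labeled = None
    for _ in range(max_redraws + 1):
        mask = rng.random(n_sites) < phys.dol
        if mask.any():
            labeled = np.flatnonzero(mask)
            break
    if labeled is None:
        raise DegenerateParticleError(
            f"no labeled site after {max_redraws} redraws (dol={phys.dol})")
    counts = _zero_truncated_poisson(phys.mean_locs_per_site, labeled.size, rng)
    points = np.repeat(sites[labeled], counts, axis=0)
    if phys.loc_precision_nm > 0:
        points = points + rng.normal(0.0, phys.loc_precision_nm, points.shape)
    theta = rng.uniform(0.0, 2 * np.pi)
    points = points @ _rot_z(theta, model.p).T
    record = {
        "true_radius_nm": model.radius_nm if radius_nm is None else radius_nm,
        "true_height_nm": model.height_nm if height_nm is None else height_nm,
        "n_localizations": int(points.shape[0]),
        "n_labeled_sites": int(labeled.size),
    }
    return Particle(points=points, id=particle_id), record


def simulate_dataset(model: StructureModel, het: HeterogeneitySpec,
                     phys: PhotophysicsSpec, n_particles: int,
                     seed: int | np.random.Generator = 0,
                     ) -> tuple[ParticleDataset, pd.DataFrame]:
    """Generate a dataset plus an aligned ground-truth table.

    Each particle draws its own shape parameters from ``het``; the returned
    DataFrame has one row per particle in dataset order with columns
    ``particle_id, true_radius_nm, true_height_nm, n_localizations,
    n_labeled_sites``. Fully reproducible for a fixed integer seed.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    particles, rows = [], []
    for i in range(n_particles):
        radius = het.radius.sample(rng) if het.radius is not None else None
        height = het.height.sample(rng) if het.height is not None else None
        if radius is not None and radius <= 0:
            raise ValueError(f"sampled nonpositive radius {radius}")
        if height is not None and height <= 0:
            raise ValueError(f"sampled nonpositive height {height}")
        particle, record = simulate_particle(
            model, phys, rng, radius_nm=radius, height_nm=height, particle_id=i)
        particles.append(particle)
        rows.append({"particle_id": i, **record})
    return (ParticleDataset(particles=particles),
            pd.DataFrame(rows))


# -- emulation presets ---------------------------------------------------------
# Descriptive targets: a few hundred particles, ~10^2 localizations per
# particle for STORM-like data, high counts for PAINT-like data, nanometre
# localization precision, NPC radius around 55 nm, NPC ring separation around
# 48.5 nm, tetrahedron heights spanning roughly 45-95 nm.

PRESETS: dict[str, dict] = {
    "npc2d": dict(
        model=StructureModel(kind="ring2d", radius_nm=55.0),
        het=HeterogeneitySpec(radius=normal(55.0, 5.0)),
        phys=PhotophysicsSpec(dol=0.6, mean_locs_per_site=31.25,
                              loc_precision_nm=3.0),
        n_particles=1399,
    ),
    "tetra3d": dict(
        model=StructureModel(kind="tetrahedron3d", height_nm=65.0,
                             base_edge_nm=100.0),
        het=HeterogeneitySpec(height=uniform(45.0, 95.0)),
        phys=PhotophysicsSpec(dol=0.9, mean_locs_per_site=250.0,
                              loc_precision_nm=2.0),
        n_particles=218,
    ),
    "npc3d": dict(
        model=StructureModel(kind="double_ring3d", radius_nm=55.0,
                             height_nm=48.5),
        het=HeterogeneitySpec(radius=normal(55.0, 2.0),
                              height=normal(48.5, 2.0)),
        phys=PhotophysicsSpec(dol=0.3, mean_locs_per_site=8.4,
                              loc_precision_nm=4.0),
        n_particles=3810,
    ),
}


def simulate_preset(name: str, seed: int = 0, n_particles: int | None = None,
                    het: HeterogeneitySpec | None = None,
                    phys: PhotophysicsSpec | None = None,
                    ) -> tuple[ParticleDataset, pd.DataFrame]:
    """Run one of the named emulation presets, with optional overrides."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return simulate_dataset(
        model=cfg["model"],
        het=het if het is not None else cfg["het"],
        phys=phys if phys is not None else cfg["phys"],
        n_particles=n_particles if n_particles is not None else cfg["n_particles"],
        seed=seed,
    )
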