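"""Reading, writing, normalizing and resampling particle-grouped localizations.

A *particle* is one segmented copy of a structure, represented by the N x p
matrix of its localization coordinates in nanometres (p = 2 or 3). Datasets
are plain CSV tables with columns ``particle_id, x_nm, y_nm[, z_nm]`` or HDF5
files with one dataset per particle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CSV_COLUMNS = ("x_nm", "y_nm", "z_nm")


class FormatError(ValueError):
    """Input file does not follow the expected localization table layout."""


class DegenerateDataError(ValueError):
    """Dataset has no spatial extent and cannot be normalized."""


@dataclass(frozen=True)
class Particle:
    """One localization point set.

    Attributes
    ----------
    points : (N, p) float array, coordinates in nm (or normalized units).
    id : opaque particle identifier.
    """

    points: np.ndarray
    id: object = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] not in (2, 3):
            raise ValueError(f"points must be (N>=1, p in {{2,3}}), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("particle contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def p(self) -> int:
        return self.points.shape[1]


@dataclass
class ParticleDataset:
    """Ordered collection of particles sharing a spatial dimension.

    ``scale_nm`` maps normalized units back to nm by multiplication;
    ``centroids_nm`` stores the per-particle centroid removed during
    normalization so the transform is invertible.
    """

    particles: list[Particle]
    p: int = 0
    scale_nm: float = 1.0
    normalized: bool = False
    centroids_nm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.particles:
            raise ValueError("empty dataset")
        dims = {pt.p for pt in self.particles}
        if len(dims) != 1:
            raise ValueError(f"particles mix spatial dimensions: {sorted(dims)}")
        self.p = dims.pop()
        if self.scale_nm <= 0:
            raise ValueError("scale_nm must be positive")

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    def __getitem__(self, i) -> Particle:
        return self.particles[i]

    @property
    def ids(self) -> list:
        return [pt.id for pt in self.particles]


# -- file formats -------------------------------------------------------------

def read_localizations(path, dialect: str = "csv") -> ParticleDataset:
    """Read a localization table; one particle per distinct ``particle_id``.

    Rows are grouped in order of first appearance; p is inferred from the
    presence of a ``z_nm`` column (CSV) or stored metadata (HDF5).
    """
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'hdf5'")


def _read_csv(path) -> ParticleDataset:
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    required = {"particle_id", "x_nm", "y_nm"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if len(table) == 0:
        raise FormatError(f"{path}: no data rows")
    coord_cols = [c for c in _CSV_COLUMNS if c in table.columns]
    extra = set(table.columns) - set(coord_cols) - {"particle_id"}
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", path, sorted(extra))
    for col in coord_cols:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.isna() & table[col].notna()
        if bad.any() or values.isna().any():
            row = int(np.flatnonzero(values.isna())[0])
            raise FormatError(
                f"{path}: non-numeric or missing {col} at data row {row}")
        table[col] = values.astype(np.float64)
    coords = table[coord_cols].to_numpy(dtype=np.float64)
    # group by particle_id in file order
    ids, first_pos = np.unique(table["particle_id"].to_numpy(), return_index=True)
    order = np.argsort(first_pos, kind="stable")
    particles = []
    id_col = table["particle_id"].to_numpy()
    for pid in ids[order]:
        particles.append(Particle(points=coords[id_col == pid], id=pid))
    return ParticleDataset(particles=particles, scale_nm=1.0, normalized=False)


def _read_hdf5(path) -> ParticleDataset:
    import h5py

    with h5py.File(path, "r") as f:
        if "particles" not in f:
            raise FormatError(f"{path}: missing /particles group")
        grp = f["particles"]
        order = grp.attrs.get("order")
        keys = [k.decode() if isinstance(k, bytes) else str(k) for k in order] \
            if order is not None else sorted(grp.keys())
        particles = [Particle(points=grp[k]["points"][()], id=k) for k in keys]
        scale = float(f.attrs.get("scale_nm", 1.0))
        normalized = bool(f.attrs.get("normalized", False))
        centroids = f["centroids_nm"][()] if "centroids_nm" in f else None
    if not particles:
        raise FormatError(f"{path}: no particles stored")
    return ParticleDataset(particles=particles, scale_nm=scale,
                           normalized=normalized, centroids_nm=centroids)


def write_localizations(dataset: ParticleDataset, path, dialect: str = "csv") -> None:
    """Write a dataset; coordinates always leave in nm (de-normalized)."""
    out = denormalize_dataset(dataset) if dataset.normalized else dataset
    if dialect == "csv":
        _write_csv(out, path)
    elif dialect == "hdf5":
        _write_hdf5(out, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'hdf5'")


def _write_csv(dataset: ParticleDataset, path) -> None:
    cols = list(_CSV_COLUMNS[: dataset.p])
    frames = []
    for i, particle in enumerate(dataset):
        pid = particle.id if particle.id is not None else i
        df = pd.DataFrame(particle.points, columns=cols)
        df.insert(0, "particle_id", pid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.9g")


def _write_hdf5(dataset: ParticleDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["p"] = dataset.p
        f.attrs["scale_nm"] = dataset.scale_nm
        f.attrs["normalized"] = dataset.normalized
        grp = f.create_group("particles")
        names = []
        for i, particle in enumerate(dataset):
            name = str(particle.id) if particle.id is not None else str(i)
            names.append(name)
            grp.create_group(name).create_dataset(
                "points", data=particle.points.astype(np.float64))
        grp.attrs["order"] = names
        if dataset.centroids_nm is not None:
            f.create_dataset("centroids_nm", data=dataset.centroids_nm)


# -- normalization ------------------------------------------------------------

def normalize_dataset(dataset: ParticleDataset) -> ParticleDataset:
    """Center each particle and scale all of them by one global factor.

    Every particle is centered at its own centroid; all particles are then
    divided by a single scale s = max over particles of the max point norm
    after centering, so each coordinate lies in [-1, 1] and relative particle
    sizes are preserved. The per-particle centroids and s are stored so the
    transform is exactly invertible.
    """
    if dataset.normalized:
        raise ValueError("dataset is already normalized")
    centroids = np.stack([p.points.mean(axis=0) for p in dataset])
    centered = [p.points - c for p, c in zip(dataset, centroids)]
    scale = max(float(np.linalg.norm(pts, axis=1).max()) for pts in centered)
    if scale == 0.0:
        raise DegenerateDataError(
            "all particles have zero spatial extent; cannot normalize")
    particles = [replace(p, points=pts / scale)
                 for p, pts in zip(dataset, centered)]
    return ParticleDataset(particles=particles, scale_nm=scale,
                           normalized=True, centroids_nm=centroids)


def denormalize_dataset(dataset: ParticleDataset) -> ParticleDataset:
    """Invert :func:`normalize_dataset` (multiply by scale, re-add centroids)."""
    if not dataset.normalized:
        return dataset
    centroids = dataset.centroids_nm
    if centroids is None:
        centroids = np.zeros((len(dataset), dataset.p))
    particles = [replace(p, points=p.points * dataset.scale_nm + c)
                 for p, c in zip(dataset, centroids)]
    return ParticleDataset(particles=particles, scale_nm=1.0, normalized=False)


# -- resampling ---------------------------------------------------------------

def resample_particle(particle: Particle, n_points: int,
                      seed: int | np.random.Generator | None = None) -> Particle:
    """Uniform resampling with replacement to a fixed point count.

    Mini-batch training needs equal point counts per particle; if the count
    already matches, the particle passes through unchanged.
    """
    if n_points <= 0:
        raise ValueError(f"n_points must be positive, got {n_points}")
    if particle.n_points == n_points:
        return particle
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, particle.n_points, size=n_points)
    return replace(particle, points=particle.points[idx])


def subsample_particle(particle: Particle, ratio: float,
                       rng: np.random.Generator) -> Particle:
    """Keep floor(ratio * N) localizations, drawn without replacement.

    ratio = 1.0 is a strict no-op so that downstream runs reproduce the
    unsubsampled pipeline bit for bit.
    """
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    if ratio == 1.0:
        return particle
    keep = int(np.floor(ratio * particle.n_points))
    if keep < 1:
        raise ValueError(
            f"ratio {ratio} leaves no localizations for particle {particle.id}")
    idx = np.sort(rng.choice(particle.n_points, size=keep, replace=False))
    return replace(particle, points=particle.points[idx])
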