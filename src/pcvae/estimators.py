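"""Model-based geometric parameter estimators.

These independent per-particle estimates (ring radius, double-ring height,
tetrahedron height) are what the latent-space orderings are validated against.
Each estimate carries a precision computed as the full width at half maximum
of the underlying sample divided by the square root of the localization
count — the standard error of the mean under a Gaussian spread. The FWHM is
taken as 2*sqrt(2 ln 2) times a robust (median-absolute-deviation) sigma, so
it is free of any histogram bin-width choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import median_abs_deviation

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class InsufficientDataError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterEstimate:
    """Scalar geometric estimate in nm with its FWHM-based standard error."""

    value: float
    precision: float
    n_localizations: int
    method: str

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("estimate is not finite")
        if self.precision < 0:
            raise ValueError("precision must be nonnegative")


def estimate_precision(values: np.ndarray) -> float:
    """FWHM of the sample divided by sqrt(N): the standard error of the mean.

    A zero-spread sample returns 0.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise InsufficientDataError("need at least 2 values")
    sigma = median_abs_deviation(values, scale="normal")
    return float(_FWHM_FACTOR * sigma / np.sqrt(values.size))


def _centered(points: np.ndarray) -> np.ndarray:
    return points - points.mean(axis=0)


def estimate_radius_2d(particle) -> ParameterEstimate:
    """Ring radius: mean radial coordinate after centering at the centroid."""
    points = np.asarray(particle.points, dtype=np.float64)
    if points.shape[0] < 2:
        raise InsufficientDataError("need at least 2 localizations")
    if points.shape[1] != 2:
        raise ValueError("estimate_radius_2d expects 2-D particles")
    r = np.linalg.norm(_centered(points), axis=1)
    return ParameterEstimate(value=float(r.mean()),
                             precision=estimate_precision(r),
                             n_localizations=points.shape[0],
                             method="radius_2d_mean")


def estimate_radius_3d(particle) -> ParameterEstimate:
    """Cylinder radius: median in-plane (x, y) radial coordinate."""
    points = np.asarray(particle.points, dtype=np.float64)
    if points.shape[0] < 2:
        raise InsufficientDataError("need at least 2 localizations")
    if points.shape[1] != 3:
        raise ValueError("estimate_radius_3d expects 3-D particles")
    r = np.linalg.norm(_centered(points)[:, :2], axis=1)
    return ParameterEstimate(value=float(np.median(r)),
                             precision=estimate_precision(r),
                             n_localizations=points.shape[0],
                             method="radius_3d_median")


def estimate_height_npc3d(particle) -> ParameterEstimate:
    """Double-ring height: difference of the median z above and below the
    central plane (the mean z of all localizations)."""
    points = np.asarray(particle.points, dtype=np.float64)
    if points.shape[1] != 3:
        raise ValueError("estimate_height_npc3d expects 3-D particles")
    z = points[:, 2]
    center = z.mean()
    above, below = z[z > center], z[z < center]
    if above.size == 0 or below.size == 0:
        raise DegenerateGeometryError(
            "all localizations on one side of the central plane")
    value = float(np.median(above) - np.median(below))
    return ParameterEstimate(value=value,
                             precision=estimate_precision(z),
                             n_localizations=points.shape[0],
                             method="height_npc3d_median_split")


def _fit_two_gaussians(z: np.ndarray, max_iter: int, tol: float,
                       var_floor: float = 1e-6) -> tuple[np.ndarray, int]:
    """EM for a two-component 1-D Gaussian mixture on raw values.

    Initialization: means at the 25th/75th percentiles, the first E-step
    assigns each point to its nearer initial mean (hard split), from which
    weights, means and variances start. A variance floor keeps fully
    separated noise-free layers (delta-like components) well defined.
    Returns the two means and the iteration count; raises on non-convergence.
    """
    init = np.percentile(z, [25.0, 75.0])
    if init[0] == init[1]:
        # heavily unbalanced mixture: both quartiles inside one layer
        init = np.array([z.min(), z.max()])
    resp_hard = np.abs(z[:, None] - init[None, :]).argmin(axis=1)
    means = np.empty(2)
    variances = np.empty(2)
    weights = np.empty(2)
    for k in range(2):
        members = z[resp_hard == k] if np.any(resp_hard == k) else z
        means[k] = members.mean()
        variances[k] = max(members.var(), var_floor)
        weights[k] = max((resp_hard == k).mean(), 1e-3)
    weights /= weights.sum()

    prev_ll = -np.inf
    for iteration in range(1, max_iter + 1):
        # E-step in log space
        log_pdf = (-0.5 * ((z[:, None] - means[None, :]) ** 2 / variances)
                   - 0.5 * np.log(2 * np.pi * variances)
                   + np.log(weights))
        norm = np.logaddexp(log_pdf[:, 0], log_pdf[:, 1])
        resp = np.exp(log_pdf - norm[:, None])
        ll = norm.mean()
        # M-step
        nk = resp.sum(axis=0) + 1e-300
        means = (resp * z[:, None]).sum(axis=0) / nk
        variances = np.maximum(
            (resp * (z[:, None] - means[None, :]) ** 2).sum(axis=0) / nk,
            var_floor)
        weights = nk / len(z)
        if abs(ll - prev_ll) < tol:
            return means, iteration
        prev_ll = ll
    raise RuntimeError(f"EM did not converge within {max_iter} iterations")


def estimate_height_tetrahedron(particle, max_iter: int = 500,
                                tol: float = 1e-8) -> ParameterEstimate:
    """Tetrahedron height: separation of a two-component Gaussian mixture
    fitted to the z-coordinates by expectation-maximization.

    The mixture is initialized at the 25th/75th z-percentiles with a variance
    floor of 1e-6 so fully separated (noise-free) layers converge cleanly.
    """
    points = np.asarray(particle.points, dtype=np.float64)
    if points.shape[0] < 10:
        raise InsufficientDataError("need at least 10 localizations")
    if points.shape[1] != 3:
        raise ValueError("estimate_height_tetrahedron expects 3-D particles")
    z = points[:, 2]
    if np.ptp(z) == 0:
        raise DegenerateGeometryError("z coordinates have zero spread")
    means, _ = _fit_two_gaussians(z, max_iter=max_iter, tol=tol)
    value = float(abs(means[1] - means[0]))
    return ParameterEstimate(value=value,
                             precision=estimate_precision(z),
                             n_localizations=points.shape[0],
                             method="height_tetra_gmm")
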