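import numpy as np
import pytest

from pcvae import (Particle, estimate_height_npc3d,
                   estimate_height_tetrahedron, estimate_precision,
                   estimate_radius_2d, estimate_radius_3d)
from pcvae.estimators import DegenerateGeometryError, InsufficientDataError

FWHM = 2 * np.sqrt(2 * np.log(2))


def ring_points(radius, n=8, z=None):
    ang = 2 * np.pi * np.arange(n) / n
    xy = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    if z is None:
        return xy
    return np.column_stack([xy, np.full(n, z)])


class TestRadius2D:
    def test_exact_on_noise_free_ring(self):
        est = estimate_radius_2d(Particle(points=ring_points(55.0)))
        assert est.value == pytest.approx(55.0, abs=1e-12)

    def test_two_symmetric_points(self):
        est = estimate_radius_2d(Particle(points=[[3.0, 0.0], [-3.0, 0.0]]))
        assert est.value == pytest.approx(3.0)

    def test_radial_mean_bias_matches_second_order_expansion(self, rng):
        # E[r] ~ R + sigma^2 / (2 R) for isotropic Gaussian noise on a ring
        R, sigma, n = 50.0, 3.0, 100_000
        ang = rng.uniform(0, 2 * np.pi, n)
        pts = R * np.column_stack([np.cos(ang), np.sin(ang)])
        pts += rng.normal(0, sigma, (n, 2))
        est = estimate_radius_2d(Particle(points=pts))
        r = np.linalg.norm(pts - pts.mean(0), axis=1)
        se = r.std(ddof=1) / np.sqrt(n)
        assert abs(est.value - (R + sigma**2 / (2 * R))) < 3 * se

    def test_requires_two_points(self):
        with pytest.raises(InsufficientDataError):
            estimate_radius_2d(Particle(points=[[0.0, 1.0]]))


class TestRadius3D:
    def test_exact_on_noise_free_cylinder(self):
        pts = np.vstack([ring_points(55.0, z=-10.0), ring_points(55.0, z=10.0)])
        est = estimate_radius_3d(Particle(points=pts))
        assert est.value == pytest.approx(55.0, abs=1e-12)

    def test_median_is_robust_to_contamination(self, rng):
        n = 1000
        ang = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([55 * np.cos(ang), 55 * np.sin(ang),
                               rng.normal(0, 5, n)])
        clean = estimate_radius_3d(Particle(points=pts)).value
        contaminated = pts.copy()
        idx = rng.choice(n, n // 10, replace=False)
        far_ang = rng.uniform(0, 2 * np.pi, n // 10)
        contaminated[idx, 0] = 200 * np.cos(far_ang)
        contaminated[idx, 1] = 200 * np.sin(far_ang)
        est = estimate_radius_3d(Particle(points=contaminated)).value
        assert abs(est - clean) < 1.0

    def test_median_convention_midpoint_of_middle_two(self):
        # 4 points at distinct radii: median = mean of 2nd and 3rd
        pts = np.array([[1.0, 0, 0], [-2.0, 0, 0], [0, 3.0, 0], [0, -4.0, 0]])
        pts = pts - pts.mean(axis=0)
        r = np.sort(np.linalg.norm(pts[:, :2], axis=1))
        est = estimate_radius_3d(Particle(points=pts + pts.mean(axis=0)))
        assert est.value == pytest.approx((r[1] + r[2]) / 2)


class TestHeightNPC3D:
    def test_two_delta_layers(self):
        pts = np.vstack([ring_points(55.0, z=-24.25),
                         ring_points(55.0, z=24.25)])
        est = estimate_height_npc3d(Particle(points=pts))
        assert est.value == pytest.approx(48.5, abs=1e-12)

    def test_two_gaussian_layers_recover_separation(self, rng):
        n = 10_000
        z = np.concatenate([rng.normal(-24.25, 3, n // 2),
                            rng.normal(24.25, 3, n // 2)])
        pts = np.column_stack([rng.normal(0, 50, n), rng.normal(0, 50, n), z])
        est = estimate_height_npc3d(Particle(points=pts))
        # median of a half-Gaussian layer ~ its mean; MC tolerance on medians
        se = 3 * 1.2533 / np.sqrt(n // 2)  # SE of a Gaussian median
        assert abs(est.value - 48.5) < 3 * 2 * se + 0.2

    def test_translation_invariance_in_z(self):
        pts = np.vstack([ring_points(55.0, z=0.0), ring_points(55.0, z=48.5)])
        a = estimate_height_npc3d(Particle(points=pts)).value
        b = estimate_height_npc3d(Particle(points=pts + [0, 0, 1234.5])).value
        assert a == pytest.approx(b, abs=1e-9)

    def test_single_z_layer_is_degenerate(self):
        pts = ring_points(55.0, z=5.0)  # every point at the same z
        with pytest.raises(DegenerateGeometryError):
            estimate_height_npc3d(Particle(points=pts))


class TestHeightTetrahedron:
    def test_separated_noiseless_layers(self):
        z = np.concatenate([np.zeros(30), np.full(10, 90.0)])
        pts = np.column_stack([np.tile([10.0, -10.0], 20),
                               np.tile([5.0, -5.0], 20), z])
        est = estimate_height_tetrahedron(Particle(points=pts))
        assert est.value == pytest.approx(90.0, abs=1e-6)

    def test_em_recovers_mixture_separation(self, rng):
        n = 10_000
        z = np.concatenate([rng.normal(0, 2, 3 * n // 4),
                            rng.normal(60, 2, n // 4)])
        pts = np.column_stack([rng.normal(0, 30, n), rng.normal(0, 30, n), z])
        est = estimate_height_tetrahedron(Particle(points=pts))
        se = 2 / np.sqrt(n // 4)
        assert abs(est.value - 60.0) < 3 * 2 * se

    def test_unequal_weights_do_not_bias_separation(self, rng):
        # 3 base sites vs 1 apex: 3:1 weight ratio
        n = 10_000
        for frac in (0.75, 0.5):
            k = int(n * frac)
            z = np.concatenate([rng.normal(0, 2, k), rng.normal(60, 2, n - k)])
            pts = np.column_stack([rng.normal(0, 30, n),
                                   rng.normal(0, 30, n), z])
            est = estimate_height_tetrahedron(Particle(points=pts))
            assert abs(est.value - 60.0) < 0.2

    def test_em_agrees_with_reference_mixture_fit(self, rng):
        # independent route: sklearn's EM on a well-conditioned noisy mixture
        from sklearn.mixture import GaussianMixture

        n = 5000
        k = n // 3
        z = np.concatenate([rng.normal(-10, 3, n - k),
                            rng.normal(55, 4, k)])
        pts = np.column_stack([rng.normal(0, 20, n), rng.normal(0, 20, n), z])
        ours = estimate_height_tetrahedron(Particle(points=pts)).value
        gmm = GaussianMixture(n_components=2, n_init=5, random_state=0,
                              tol=1e-8, max_iter=500).fit(z.reshape(-1, 1))
        reference = abs(gmm.means_[1, 0] - gmm.means_[0, 0])
        assert ours == pytest.approx(reference, abs=0.05)

    def test_zero_spread_rejected(self):
        pts = np.column_stack([np.arange(20.0), np.arange(20.0),
                               np.full(20, 7.0)])
        with pytest.raises(DegenerateGeometryError):
            estimate_height_tetrahedron(Particle(points=pts))


class TestPrecision:
    def test_gaussian_sample_fwhm_over_sqrt_n(self, rng):
        sigma, n = 10.0, 100
        reps = 400
        vals = np.array([
            estimate_precision(rng.normal(0, sigma, n)) for _ in range(reps)])
        expected = FWHM * sigma / np.sqrt(n)
        assert abs(vals.mean() - expected) < 4 * vals.std(ddof=1) / np.sqrt(reps)

    def test_quadrupling_n_halves_precision(self, rng):
        base = rng.normal(0, 10, 250)
        big = np.tile(base, 4)
        assert estimate_precision(big) == pytest.approx(
            estimate_precision(base) / 2)

    def test_constant_sample_gives_zero(self):
        assert estimate_precision(np.full(50, 3.3)) == 0.0


class TestRigidMotionInvariance:
    def test_estimators_invariant_to_z_rotation_and_translation(self, rng):
        pts3 = np.vstack([ring_points(55.0, n=16, z=-24.25),
                          ring_points(55.0, n=16, z=24.25)])
        pts3 += rng.normal(0, 1.0, pts3.shape)
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        shift = rng.normal(0, 100, 3)
        moved = pts3 @ rot.T + shift
        for estimator in (estimate_radius_3d, estimate_height_npc3d):
            a = estimator(Particle(points=pts3)).value
            b = estimator(Particle(points=moved)).value
            assert a == pytest.approx(b, abs=1e-9)

        pts2 = ring_points(55.0) + rng.normal(0, 1.0, (8, 2))
        rot2 = np.array([[c, -s], [s, c]])
        a = estimate_radius_2d(Particle(points=pts2)).value
        b = estimate_radius_2d(Particle(points=pts2 @ rot2.T + [37.0, -11.0])).value
        assert a == pytest.approx(b, abs=1e-9)
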