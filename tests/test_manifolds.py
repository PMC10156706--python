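"""Manifold estimation, perturbation derivatives and geometry statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import orthogonal_procrustes

from vermis.manifolds import (
    PopulationManifold,
    align_cca,
    eigenvalue_stability,
    encoding_dimensionality,
    manifold_size,
    rotation_speed,
    slope_angle,
)


def smooth_patterns(rng, k, T=400):
    t = np.linspace(-250, 400, T)
    out = []
    for _ in range(k):
        c = rng.uniform(-200, 350, 4)
        w = rng.uniform(20, 80, 4)
        a = rng.normal(0, 1, 4)
        out.append(sum(ai * np.exp(-0.5 * ((t - ci) / wi) ** 2)
                       for ai, ci, wi in zip(a, c, w)))
    return np.array(out)


@pytest.fixture(scope="module")
def synthetic_population():
    rng = np.random.default_rng(0)
    N, K0 = 40, 6
    B = smooth_patterns(rng, K0)
    load = rng.normal(0, 1, (N, K0)) * np.array([30, 18, 10, 6, 3, 2])
    R0 = load @ B
    D = rng.normal(0, 1, (N, K0 + 2)) @ smooth_patterns(rng, K0 + 2) * 0.5
    return R0, D


class TestBaseManifold:
    def test_exact_rank_two(self):
        rng = np.random.default_rng(1)
        B = smooth_patterns(rng, 2)
        R0 = rng.normal(0, 1, (20, 2)) @ B
        man = PopulationManifold().fit(R0)
        assert man.K_ == 2
        assert man.explained_variance_ratio_[:2].sum() == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(man.W_ @ man.P_, R0, atol=1e-8)

    def test_orthonormal_loadings(self, synthetic_population):
        R0, _ = synthetic_population
        man = PopulationManifold().fit(R0)
        assert np.allclose(man.W_.T @ man.W_, np.eye(man.K_), atol=1e-8)

    def test_sign_convention_deterministic(self, synthetic_population):
        R0, _ = synthetic_population
        a = PopulationManifold().fit(R0)
        b = PopulationManifold().fit(R0.copy())
        assert np.array_equal(a.W_, b.W_)
        k = np.argmax(np.abs(a.W_), axis=0)
        assert (a.W_[k, np.arange(a.K_)] > 0).all()

    def test_noise_raises_dimensionality(self, synthetic_population):
        rng = np.random.default_rng(2)
        B = smooth_patterns(rng, 2)
        R0 = rng.normal(0, 1, (30, 2)) @ B
        k_clean = PopulationManifold().fit(R0).K_
        noisy = R0 + 0.5 * np.linalg.norm(R0) / np.sqrt(R0.size) * rng.standard_normal(R0.shape)
        k_noisy = PopulationManifold().fit(noisy).K_
        assert k_clean == 2
        assert k_noisy >= k_clean
        # cross-validation curve has its elbow at the true rank
        errs = PopulationManifold(n_components=6).fit(noisy).cross_validation_curve()
        drops = -np.diff(errs)
        assert np.argmax(drops < 0.25 * drops[0]) <= 2

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            PopulationManifold().fit(np.zeros((5, 50)))


class TestPerturbationDerivatives:
    def test_pure_scaling(self, synthetic_population):
        """A perturbation proportional to R0 leaves the subspace invariant."""
        R0, _ = synthetic_population
        c = 0.03
        man = PopulationManifold().fit(R0, {"z": c * R0})
        assert np.abs(man.dWdz_["z"]).max() < 1e-8
        assert np.allclose(man.dPdz_["z"], c * man.P_, atol=1e-6)

    def test_in_span_perturbation_residual_term_vanishes(self):
        rng = np.random.default_rng(3)
        B = smooth_patterns(rng, 3)
        R0 = rng.normal(0, 1, (25, 3)) @ B          # exactly rank 3
        man = PopulationManifold(n_components=3).fit(R0)
        D = man.W_ @ rng.normal(0, 1, (3, B.shape[1]))  # within span(W)
        man.compute_derivatives({"z": D})
        assert np.allclose(man.dPdz_["z"], man.W_.T @ D, atol=1e-6)

    def test_oracle_agreement_and_convergence(self, synthetic_population):
        """First-order prediction matches a direct PCA re-fit; halving dz
        quarters the error."""
        R0, D = synthetic_population
        sd = 0.1 * np.linalg.norm(R0) / np.linalg.norm(D)
        man = PopulationManifold().fit(R0, {"z": D})

        def rel_err(dz):
            pred = man.evaluate_trajectory({"z": dz})
            ref = PopulationManifold(n_components=man.K_).fit(R0 + dz * D)
            om, _ = orthogonal_procrustes(ref.W_, man.W_)
            return np.linalg.norm(pred - om.T @ ref.P_) / np.linalg.norm(man.P_)

        e1, e2 = rel_err(0.5 * sd), rel_err(0.25 * sd)
        assert e1 < 0.05
        assert e1 / e2 == pytest.approx(4.0, rel=0.3)

    def test_finite_difference_agrees(self, synthetic_population):
        R0, D = synthetic_population
        a = PopulationManifold(derivative_method="perturbation").fit(R0, {"z": D})
        b = PopulationManifold(derivative_method="finite_difference").fit(R0, {"z": D})
        rel = np.linalg.norm(a.dPdz_["z"] - b.dPdz_["z"]) / np.linalg.norm(a.dPdz_["z"])
        assert rel < 1e-4

    def test_evaluate_affine(self, synthetic_population):
        R0, D = synthetic_population
        man = PopulationManifold().fit(R0, {"z": D})
        mid = 0.5 * (man.evaluate_trajectory({"z": 0.0}) + man.evaluate_trajectory({"z": 2.0}))
        assert np.allclose(mid, man.evaluate_trajectory({"z": 1.0}), atol=1e-10)

    def test_unknown_parameter(self, synthetic_population):
        R0, D = synthetic_population
        man = PopulationManifold().fit(R0, {"z": D})
        with pytest.raises(KeyError):
            man.evaluate_trajectory({"other": 1.0})


class TestEigenvalueStability:
    def test_zero_perturbation(self, synthetic_population):
        R0, D = synthetic_population
        rep = eigenvalue_stability(R0, D, [0.0])
        assert rep["max_relative_change"] == pytest.approx(0.0, abs=1e-10)

    def test_scaling_closed_form(self, synthetic_population):
        R0, _ = synthetic_population
        c, dz = 1.0, 0.07
        rep = eigenvalue_stability(R0, c * R0, [dz])
        assert np.allclose(rep["eigenvalues"][0], rep["base"] * (1 + c * dz) ** 2,
                           rtol=1e-8)

    def test_first_order_taylor(self, synthetic_population):
        R0, D = synthetic_population
        sd = 0.05 * np.linalg.norm(R0) / np.linalg.norm(D)
        errs = []
        for dz in (sd, sd / 2):
            rep = eigenvalue_stability(R0, D, [dz], n_eigs=3)
            errs.append(np.abs(rep["eigenvalues"][0] - rep["first_order"][0]).max())
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.4)


class TestGeometry:
    def test_circle_area(self):
        th = np.radians(np.arange(0, 360, 1.0))
        xy = np.c_[np.cos(th), np.sin(th)]
        assert manifold_size(xy) == pytest.approx(np.pi, rel=1e-3)

    def test_ellipse_area(self):
        th = np.radians(np.arange(0, 360, 1.0))
        xy = np.c_[3 * np.cos(th), 2 * np.sin(th)]
        assert manifold_size(xy) == pytest.approx(6 * np.pi, rel=1e-3)

    def test_polygon_matches_shapely(self):
        from shapely.geometry import Polygon

        rng = np.random.default_rng(0)
        th = np.sort(rng.uniform(0, 2 * np.pi, 25))
        r = rng.uniform(0.5, 2.0, 25)
        xy = np.c_[r * np.cos(th), r * np.sin(th)] + [0.3, -0.2]
        assert manifold_size(xy) == pytest.approx(Polygon(xy).area, abs=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(angle=st.floats(0, 2 * np.pi))
    def test_rotation_invariance(self, angle):
        th = np.radians(np.arange(0, 360, 5.0))
        xy = np.c_[2 * np.cos(th), np.sin(th)]
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        assert manifold_size(xy @ R.T) == pytest.approx(manifold_size(xy), rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            manifold_size(np.zeros((2, 2)))


def _three_quarter_loop(t_total=300.0, n=301, warp=None, sweep=270.0):
    """Circle of radius 1 about (1, 0) traversed CCW from phase -180."""
    s = np.linspace(0.0, 1.0, n)
    if warp is not None:
        s = warp(s)
    ang = np.radians(-180 + sweep * s)
    t = -250 + np.linspace(0, t_total, n)
    return np.c_[1 + np.cos(ang), np.sin(ang)], t


class TestRotationSpeed:
    def test_uniform_three_quarter_turn(self):
        xy, t = _three_quarter_loop(300.0)
        speed, t34 = rotation_speed(xy, t)
        assert speed == pytest.approx(0.9, abs=1e-6)
        assert t34 == pytest.approx(300.0, abs=1e-6)

    def test_time_scaling_halves_speed(self):
        xy, t = _three_quarter_loop(600.0)
        assert rotation_speed(xy, t)[0] == pytest.approx(0.45, abs=1e-6)

    def test_nonuniform_matches_dense_search(self):
        # non-uniform rotation sweeping past +90 deg mid-trajectory
        warp = lambda s: s**1.5
        xy, t = _three_quarter_loop(300.0, n=121, warp=warp, sweep=310.0)
        speed, t34 = rotation_speed(xy, t)
        # brute force: on dense resampling, first time the phase reaches +90
        xyd, td = _three_quarter_loop(300.0, n=30001, warp=warp, sweep=310.0)
        ang = np.degrees(np.unwrap(np.arctan2(xyd[:, 1], xyd[:, 0] - 1.0)))
        if ang[0] > 0:
            ang -= 360.0
        t_cross = td[np.flatnonzero(ang >= 90.0)[0]]
        assert t34 == pytest.approx(t_cross - td[0], abs=1.0)
        assert speed == pytest.approx(270.0 / t34)

    def test_incomplete_rotation_sentinel(self):
        th = np.radians(np.linspace(-180, -90, 50))
        xy = np.c_[1 + np.cos(th), np.sin(th)]
        speed, t34 = rotation_speed(xy, np.linspace(-250, 0, 50))
        assert np.isnan(speed) and np.isnan(t34)

    def test_clockwise_loop_mirrored(self):
        xy, t = _three_quarter_loop(300.0)
        xy_cw = np.c_[xy[:, 0], -xy[:, 1]]
        assert rotation_speed(xy_cw, t)[0] == pytest.approx(0.9, abs=1e-6)


class TestSlopeAngle:
    def test_unit_slope_is_45(self):
        assert slope_angle([1, 2, 3], [1, 2, 3], (1.0, 1.0)) == pytest.approx(45.0)

    def test_constant_speed_zero(self):
        assert slope_angle([1, 2, 3], [5, 5, 5], (1.0, 1.0)) == pytest.approx(0.0)

    def test_constant_size_ninety(self):
        assert slope_angle([2, 2, 2], [1, 2, 3], (1.0, 1.0)) == pytest.approx(90.0)

    def test_normalization(self):
        # normalizing by control SDs makes the angle scale-free
        a = slope_angle([10, 20, 30], [0.1, 0.2, 0.3], (np.std([10, 20, 30]), np.std([0.1, 0.2, 0.3])))
        assert a == pytest.approx(45.0)

    def test_zero_control_sd_rejected(self):
        with pytest.raises(ValueError):
            slope_angle([1, 2], [1, 2], (0.0, 1.0))


class TestCCA:
    def test_rotated_copy_perfect(self):
        rng = np.random.default_rng(0)
        P = rng.standard_normal((3, 150))
        R, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rho = align_cca(P, R @ P)
        assert np.allclose(rho, 1.0, atol=1e-8)

    def test_independent_noise_below_null(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((3, 200))
        B = rng.standard_normal((3, 200))
        rho = align_cca(A, B)
        null = []
        for _ in range(200):
            perm = rng.permutation(200)
            null.append(align_cca(A, B[:, perm])[0])
        assert rho[0] <= np.quantile(null, 0.95) + 0.05

    def test_sorted_descending(self):
        rng = np.random.default_rng(2)
        rho = align_cca(rng.standard_normal((4, 100)), rng.standard_normal((3, 100)))
        assert np.all(np.diff(rho) <= 1e-12)

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError):
            align_cca(np.ones((2, 50)), np.random.default_rng(0).standard_normal((2, 50)))


class TestEncodingDimensionality:
    def test_rank_one(self):
        rng = np.random.default_rng(0)
        D = np.outer(rng.standard_normal(20), rng.standard_normal(100))
        assert encoding_dimensionality(D, 0.99) == 1

    def test_monotone_in_target(self, synthetic_population):
        _, D = synthetic_population
        ds = [encoding_dimensionality(D, f) for f in (0.5, 0.7, 0.9, 0.99)]
        assert all(a <= b for a, b in zip(ds, ds[1:]))

    def test_heterogeneous_needs_more_dims(self):
        rng = np.random.default_rng(3)
        B = smooth_patterns(rng, 10)
        flat = rng.normal(0, 1, (30, 10)) * np.ones(10) @ B       # flat spectrum
        steep = rng.normal(0, 1, (30, 10)) * (1.0 / np.arange(1, 11) ** 2) @ B
        assert encoding_dimensionality(flat, 0.78) > encoding_dimensionality(steep, 0.78)
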