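"""Four-shell forward model: coefficients, potentials, closed-form energies."""

import numpy as np
import pytest

from headspectra.sphere_forward import (
    MM,
    C_of_l,
    Dipole,
    ShellModel,
    forward_potential,
    rotate_to_canonical,
    term_energies,
    term_energy,
    term_potential,
    total_energy,
)

from conftest import sphere_quadrature


def mpmath_surface_gain(l, model, dps=None):
    """Independent extended-precision solve of the shell boundary-value problem.

    Seven unknown radial coefficients (region 1 homogeneous part; regions
    2-4 both parts) from potential/flux continuity and the insulating outer
    boundary; returns the same dimensionless gain the package computes via
    its Moebius recursion.
    """
    from mpmath import lu_solve, matrix, mp

    mp.dps = dps or max(80, 6 * l)
    R1, R2, R3, R4 = [mp.mpf(r) for r in model.radii]
    s1, s2, s3, s4 = [mp.mpf(s) for s in model.conductivities]
    M = matrix(7, 7)
    rhs = matrix(7, 1)
    rows = [
        ([R1**l, -(R1**l), -(R1 ** -(l + 1)), 0, 0, 0, 0], -(R1 ** -(l + 1))),
        (
            [s1 * l * R1 ** (l - 1), -s2 * l * R1 ** (l - 1),
             s2 * (l + 1) * R1 ** -(l + 2), 0, 0, 0, 0],
            s1 * (l + 1) * R1 ** -(l + 2),
        ),
        ([0, R2**l, R2 ** -(l + 1), -(R2**l), -(R2 ** -(l + 1)), 0, 0], 0),
        (
            [0, s2 * l * R2 ** (l - 1), -s2 * (l + 1) * R2 ** -(l + 2),
             -s3 * l * R2 ** (l - 1), s3 * (l + 1) * R2 ** -(l + 2), 0, 0],
            0,
        ),
        ([0, 0, 0, R3**l, R3 ** -(l + 1), -(R3**l), -(R3 ** -(l + 1))], 0),
        (
            [0, 0, 0, s3 * l * R3 ** (l - 1), -s3 * (l + 1) * R3 ** -(l + 2),
             -s4 * l * R3 ** (l - 1), s4 * (l + 1) * R3 ** -(l + 2)],
            0,
        ),
        ([0, 0, 0, 0, 0, l * R4 ** (l - 1), -(l + 1) * R4 ** -(l + 2)], 0),
    ]
    for i, (row, r) in enumerate(rows):
        for j, v in enumerate(row):
            M[i, j] = v
        rhs[i] = r
    sol = lu_solve(M, rhs)
    V = sol[5] * R4**l + sol[6] * R4 ** -(l + 1)
    return V * R4 ** (l + 1)


def mpmath_C_of_l(l, model):
    from mpmath import mp, mpf

    s = model.conductivities
    G = mpmath_surface_gain(l, model)
    return (mpf(s[0]) / mpf(s[3])) * mpf(2 * l + 1) ** 4 / (l * G)


def homogeneous_potential(dipole, sigma, radius_mm, points_mm):
    """Closed-form scalp potential of a dipole in a homogeneous insulated sphere.

    Built from Legendre generating functions (no series truncation):
    with f = b/R, x = cos(theta) in the frame where the source sits on +z,

        4 pi sigma R^2 V = 2 A + B
        A = (mz (x - f) + mt sin(theta) cos(phi')) / s^3
        B = mz (1/s - 1)/f + mt cos(phi') sin(theta) (s + 1)/(s (1 - f x + s))

    where s = sqrt(1 - 2 f x + f^2) and phi' is the azimuth relative to the
    tangential moment direction.
    """
    pos = np.asarray(dipole.position, dtype=float)
    mom = np.asarray(dipole.moment, dtype=float)
    b = np.linalg.norm(pos)
    assert b > 0
    f = b / radius_mm
    zhat = pos / b
    mz = float(mom @ zhat)
    t = mom - mz * zhat
    mt = np.linalg.norm(t)
    xhat = t / mt if mt > 0 else np.array([1.0, 0, 0])
    pts = np.asarray(points_mm, dtype=float) / radius_mm
    x = pts @ zhat
    sin_cos = pts @ xhat  # sin(theta) cos(phi')
    s = np.sqrt(1.0 - 2.0 * f * x + f * f)
    A = (mz * (x - f) + mt * sin_cos) / s**3
    B = mz * (1.0 / s - 1.0) / f + mt * sin_cos * (s + 1.0) / (s * (1.0 - f * x + s))
    R_m = radius_mm * MM
    return (2.0 * A + B) / (4.0 * np.pi * sigma * R_m**2)


class TestShellModel:
    def test_default_parameters(self, model):
        assert model.radii == (80.0, 81.0, 86.0, 92.0)
        assert model.conductivity_ratios == pytest.approx(
            (0.33 / 1.79, 1.79 / 0.0066, 0.0066 / 0.33)
        )

    @pytest.mark.parametrize(
        "radii",
        [(81, 80, 86, 92), (80, 80, 86, 92), (-80, 81, 86, 92)],
    )
    def test_invalid_radii_rejected(self, radii):
        with pytest.raises(ValueError):
            ShellModel(radii=radii)

    def test_invalid_conductivities_rejected(self):
        with pytest.raises(ValueError):
            ShellModel(conductivities=(0.33, -1.0, 0.0066, 0.33))


class TestShellCoefficient:
    def test_equal_conductivities_reduce_to_cube(self):
        hom = ShellModel(conductivities=(0.4, 0.4, 0.4, 0.4))
        ls = np.arange(1, 200)
        np.testing.assert_allclose(
            C_of_l(ls, hom), (2.0 * ls + 1.0) ** 3, rtol=1e-12
        )

    @pytest.mark.parametrize("l", [1, 2, 5, 30])
    def test_matches_extended_precision_solve(self, l, model):
        ours = C_of_l(l, model)
        exact = float(mpmath_C_of_l(l, model))
        assert ours == pytest.approx(exact, rel=1e-12)

    def test_stable_to_large_degree(self, model):
        ls = np.arange(1, 601)
        C = C_of_l(ls, model)
        assert np.all(np.isfinite(C)) and np.all(C > 0)

    def test_degree_below_one_rejected(self, model):
        with pytest.raises(ValueError):
            C_of_l(0, model)


class TestForwardPotential:
    def test_reduces_to_homogeneous_sphere(self):
        hom = ShellModel(conductivities=(0.33, 0.33, 0.33, 0.33))
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((40, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * hom.R4
        for d in (
            Dipole([0, 0, 60.0], [0, 0, 1.0]),
            Dipole([0, 0, 60.0], [1.0, 0, 0]),
            Dipole([10.0, -25.0, 40.0], [0.3, 0.5, -0.8]),
        ):
            # tight series cut: the pointwise truncation error is a few
            # orders above the energy-tail tolerance near the source pole
            ours = forward_potential(d, hom, pts, tol=1e-20).values
            oracle = homogeneous_potential(d, 0.33, hom.R4, pts)
            np.testing.assert_allclose(
                ours, oracle, rtol=1e-7, atol=1e-7 * np.abs(oracle).max()
            )

    def test_center_dipole_is_pure_degree_one(self, model):
        d = Dipole([0.0, 0, 0], [0, 0, 1.0])
        pts = np.array([[0, 0, 92.0], [92.0, 0, 0], [0, 65.0537, -65.0537]])
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 92.0
        res = forward_potential(d, model, pts)
        t1 = term_potential(1, d, model, pts)
        np.testing.assert_allclose(res.values, t1.values, rtol=1e-12)
        assert term_energy(2, d, model) == 0.0
        assert term_energy(5, d, model) == 0.0

    def test_px_dipole_antisymmetric_in_phi(self, model):
        d = Dipole([0, 0, 50.0], [1.0, 0, 0])
        theta = np.full(8, 1.1)
        phi = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = 92.0 * np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        anti = 92.0 * np.column_stack(
            [np.sin(theta) * np.cos(phi + np.pi), np.sin(theta) * np.sin(phi + np.pi), np.cos(theta)]
        )
        v = forward_potential(d, model, pts).values
        va = forward_potential(d, model, anti).values
        np.testing.assert_allclose(va, -v, atol=1e-12 * np.abs(v).max())

    def test_pz_dipole_independent_of_phi(self, model):
        d = Dipole([0, 0, 50.0], [0, 0, 1.0])
        phi = np.linspace(0, 2 * np.pi, 13)
        pts = 92.0 * np.column_stack(
            [np.sin(0.8) * np.cos(phi), np.sin(0.8) * np.sin(phi), np.full_like(phi, np.cos(0.8))]
        )
        v = forward_potential(d, model, pts).values
        assert np.ptp(v) < 1e-12 * np.abs(v).max()

    def test_rotation_invariance(self, model):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((30, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 92.0
        d = Dipole([20.0, -10.0, 55.0], [0.2, 0.9, -0.4])
        v = forward_potential(d, model, pts).values
        # joint rotation of dipole and evaluation points
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        d_rot = Dipole(R @ d.position, R @ d.moment)
        v_rot = forward_potential(d_rot, model, pts @ R.T).values
        np.testing.assert_allclose(v_rot, v, atol=1e-8 * np.abs(v).max())

    def test_points_off_surface_rejected(self, model):
        d = Dipole([0, 0, 50.0], [0, 0, 1.0])
        with pytest.raises(ValueError):
            forward_potential(d, model, np.array([[0, 0, 91.0]]))

    def test_convergence_metadata(self, model):
        d = Dipole([0, 0, 76.0], [0, 0, 1.0])
        res = forward_potential(d, model, np.array([[0, 0, 92.0]]), tol=1e-10)
        assert res.converged
        assert res.tail_fraction <= 1e-10
        assert 10 < res.l_used < 600


class TestRotateToCanonical:
    def test_identity_for_canonical_radial_dipole(self):
        d = Dipole([0, 0, 40.0], [0, 0, 1.0])
        can, R = rotate_to_canonical(d)
        np.testing.assert_allclose(R, np.eye(3))
        np.testing.assert_allclose(can.moment, [0, 0, 1.0])

    def test_roundtrip_is_identity(self):
        d = Dipole([12.0, -7.0, 30.0], [0.1, -0.9, 0.4])
        can, R = rotate_to_canonical(d)
        np.testing.assert_allclose(R.T @ can.position, d.position, atol=1e-12)
        np.testing.assert_allclose(R.T @ can.moment, d.moment, atol=1e-12)
        assert can.position[2] == pytest.approx(np.linalg.norm(d.position))
        assert abs(can.position[0]) < 1e-9 and abs(can.position[1]) < 1e-9

    def test_energy_invariant_under_tangential_azimuth(self, model):
        energies = []
        for az in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            d = Dipole([0, 0, 60.0], [np.cos(az), np.sin(az), 0.0])
            energies.append(total_energy(d, model)[0])
        assert np.ptp(energies) < 1e-12 * np.mean(energies)


class TestTermEnergies:
    @pytest.mark.parametrize("l", [1, 2, 3, 7])
    def test_closed_form_matches_quadrature(self, l, model):
        d = Dipole([0, 0, 55.0], [0.6, 0.0, 0.8])
        pts, W = sphere_quadrature(model.R4)
        tp = term_potential(l, d, model, pts)
        E_quad = float(np.sum(W * tp.values**2))
        assert tp.energy == pytest.approx(E_quad, rel=1e-8)

    def test_term_energies_additive(self, model):
        # Legendre orthogonality: quadrature of squared total = sum of terms
        d = Dipole([0, 0, 70.0], [0.0, 0.6, 0.8])
        pts, W = sphere_quadrature(model.R4)
        v = forward_potential(d, model, pts).values
        E_quad = float(np.sum(W * v**2))
        E_sum, _ = total_energy(d, model)
        assert E_sum == pytest.approx(E_quad, rel=1e-6)

    def test_energy_monotone_with_eccentricity(self, model):
        for orient, mom in (("radial", [0, 0, 1.0]), ("tangential", [1.0, 0, 0])):
            E = [total_energy(Dipole([0, 0, r], mom), model)[0]
                 for r in np.arange(4.0, 77.0, 4.0)]
            assert np.all(np.diff(E) > 0), orient

    def test_degree_one_energy_same_for_all_depths_and_orientations(self, model):
        ref = term_energy(1, Dipole([0, 0, 0.0], [0, 0, 1.0]), model)
        for r in (10.0, 40.0, 76.0):
            for mom in ([0, 0, 1.0], [1.0, 0, 0]):
                assert term_energy(1, Dipole([0, 0, r], mom), model) == pytest.approx(
                    ref, rel=1e-12
                )

    def test_no_dc_component_on_closed_sphere(self, model):
        pts, W = sphere_quadrature(model.R4)
        for d in (Dipole([0, 0, 76.0], [0, 0, 1.0]), Dipole([0, 0, 40.0], [1.0, 0, 0])):
            v = forward_potential(d, model, pts).values
            E = np.sum(W * v**2)
            mean = np.sum(W * v) / np.sum(W)
            assert abs(mean) < 1e-8 * np.sqrt(E / np.sum(W))

    def test_invalid_degree_rejected(self, model):
        with pytest.raises(ValueError):
            term_energy(0, Dipole([0, 0, 10.0], [0, 0, 1.0]), model)

    def test_dipole_outside_inner_shell_rejected(self, model):
        with pytest.raises(ValueError):
            total_energy(Dipole([0, 0, 85.0], [0, 0, 1.0]), model)
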