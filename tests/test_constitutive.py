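import numpy as np
import pytest

from cartimech.constitutive import (
    FRPEParams,
    MeniscusParams,
    arcade_direction,
    effective_stress,
    fibril_stress_1d,
    matrix_stress,
    meniscus_elasticity_tensor,
    rotate_voigt_stiffness,
)


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]  # proper rotation, not a reflection
    return Q


# ---------------------------------------------------------------------------
# Benninghoff arcade
# ---------------------------------------------------------------------------
class TestArcade:
    n = np.array([0.0, 0.0, 1.0])
    t = np.array([1.0, 0.0, 0.0])

    def test_superficial_zone_follows_split_line(self):
        assert np.allclose(arcade_direction(0.0, self.n, self.t), self.t)
        assert np.allclose(arcade_direction(0.10, self.n, self.t), self.t)

    def test_deep_zone_points_into_bone(self):
        assert np.allclose(arcade_direction(1.0, self.n, self.t), -self.n)
        assert np.allclose(arcade_direction(0.85, self.n, self.t), -self.n)

    def test_unit_norm_throughout_the_arcade(self):
        d = np.linspace(0, 1, 101)
        out = arcade_direction(d, self.n, self.t)
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-10)

    def test_midzone_interpolates_continuously(self):
        d = np.linspace(0.15, 0.70, 56)
        out = arcade_direction(d, self.n, self.t)
        steps = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert steps.max() < 0.05  # no jumps

    def test_depth_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            arcade_direction(1.2, self.n, self.t)

    def test_non_tangent_split_line_rejected(self):
        with pytest.raises(ValueError, match="tangent"):
            arcade_direction(0.5, self.n, self.n)


# ---------------------------------------------------------------------------
# fibril law
# ---------------------------------------------------------------------------
class TestFibril:
    def test_tension_only(self):
        p = FRPEParams()
        assert fibril_stress_1d(-0.1, p) == 0.0
        assert fibril_stress_1d(0.0, p) == 0.0

    def test_initial_slope_is_E0(self):
        p = FRPEParams(fibril_modulus_initial_MPa=0.47,
                       fibril_modulus_strain_dependent_MPa=150.0)
        h = 1e-8
        slope = fibril_stress_1d(h, p) / h
        assert np.isclose(slope, 0.47, rtol=1e-5)

    def test_strain_stiffening_form(self):
        p = FRPEParams(fibril_modulus_initial_MPa=2.0,
                       fibril_modulus_strain_dependent_MPa=100.0)
        assert np.isclose(fibril_stress_1d(0.05, p), (2.0 + 100.0 * 0.05) * 0.05)

    def test_monotone_non_decreasing(self):
        p = FRPEParams()
        eps = np.linspace(-0.5, 0.5, 201)
        s = fibril_stress_1d(eps, p)
        assert np.all(np.diff(s) >= 0)

    def test_overcompression_rejected(self):
        with pytest.raises(ValueError):
            fibril_stress_1d(-1.5, FRPEParams())


# ---------------------------------------------------------------------------
# Neo-Hookean matrix
# ---------------------------------------------------------------------------
class TestMatrix:
    p = FRPEParams.from_matrix_EnU(0.31, 0.42)

    def test_zero_stress_at_identity(self):
        assert np.allclose(matrix_stress(np.eye(3), self.p), 0.0)

    def test_frame_indifference_pure_rotation(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            R = random_rotation(rng)
            assert np.allclose(matrix_stress(R, self.p), 0.0, atol=1e-12)

    def test_small_strain_tangent_matches_isotropic_moduli(self):
        # numerical tangent at identity vs lambda/mu of E = 0.31, nu = 0.42
        E, nu = 0.31, 0.42
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        h = 1e-6
        C = np.zeros((3, 3, 3, 3))
        for k in range(3):
            for l in range(3):
                F = np.eye(3)
                F[k, l] += h
                C[:, :, k, l] = matrix_stress(F, self.p) / h
        Csym = 0.5 * (C + np.swapaxes(C, 2, 3))
        I = np.eye(3)
        C_iso = (lam * np.einsum("ij,kl->ijkl", I, I)
                 + mu * (np.einsum("ik,jl->ijkl", I, I) + np.einsum("il,jk->ijkl", I, I)))
        assert np.max(np.abs(Csym - C_iso)) < 1e-3 * np.max(np.abs(C_iso))

    def test_inversion_carries_element_ids(self):
        F = np.stack([np.eye(3), -np.eye(3)])
        from cartimech.constitutive import ElementInversionError

        with pytest.raises(ElementInversionError) as exc:
            matrix_stress(F, self.p)
        assert 1 in exc.value.element_ids


# ---------------------------------------------------------------------------
# fibril-reinforced composite
# ---------------------------------------------------------------------------
class TestEffectiveStress:
    a0 = np.array([1.0, 0.0, 0.0])

    def test_zero_state(self):
        sig, fib = effective_stress(np.eye(3), self.a0, FRPEParams())
        assert np.allclose(sig, 0.0)
        assert fib == pytest.approx(0.0)

    def test_compression_along_fibril_leaves_matrix_only(self):
        p = FRPEParams(primary_fibril_density_fraction=1.0, n_secondary_directions=0)
        F = np.diag([0.95, 1.0, 1.0])
        sig, fib = effective_stress(F, self.a0, p)
        assert fib == pytest.approx(-0.05)
        assert np.allclose(sig, matrix_stress(F, p), atol=1e-12)

    def test_tension_along_fibril_adds_projected_1d_stress(self):
        p = FRPEParams(primary_fibril_density_fraction=1.0, n_secondary_directions=0)
        F = np.diag([1.02, 1.0, 1.0])
        sig, fib = effective_stress(F, self.a0, p)
        diff = sig - matrix_stress(F, p)
        expect = fibril_stress_1d(0.02, p) * np.outer(self.a0, self.a0)
        assert fib == pytest.approx(0.02)
        assert np.max(np.abs(diff - expect)) < 1e-8

    def test_objectivity_under_superposed_rotation(self):
        p = FRPEParams()
        rng = np.random.default_rng(1)
        F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        assert np.linalg.det(F) > 0
        sig, fib = effective_stress(F, self.a0, p)
        for _ in range(3):
            R = random_rotation(rng)
            sig_r, fib_r = effective_stress(R @ F, self.a0, p)
            assert np.allclose(sig_r, R @ sig @ R.T, atol=1e-10)
            assert np.isclose(fib_r, fib, atol=1e-12)

    def test_rate_independence_of_the_law(self):
        # elastic fibrils: stress depends on F only, not on any rate input
        p = FRPEParams()
        F = np.diag([1.03, 0.99, 0.98])
        s1, _ = effective_stress(F, self.a0, p)
        s2, _ = effective_stress(F.copy(), self.a0, p)
        assert np.array_equal(s1, s2)


# ---------------------------------------------------------------------------
# meniscus
# ---------------------------------------------------------------------------
class TestMeniscus:
    def test_degenerate_parameters_reduce_to_isotropy(self):
        E, nu = 20.0, 0.2
        p = MeniscusParams(E_circumferential_MPa=E, E_transverse_MPa=E,
                           G_MPa=E / (2 * (1 + nu)), nu_in_plane=nu, nu_out_of_plane=nu)
        C, _ = meniscus_elasticity_tensor(p, np.array([1.0, 0, 0]))
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        expect = np.zeros((6, 6))
        expect[:3, :3] = lam
        expect[np.diag_indices(3)] = lam + 2 * mu
        expect[3, 3] = expect[4, 4] = expect[5, 5] = mu
        assert np.allclose(C, expect, rtol=1e-10)

    def test_uniaxial_stress_along_fibre_recovers_Ec(self):
        p = MeniscusParams()
        C, _ = meniscus_elasticity_tensor(p, np.array([1.0, 0, 0]))
        S = np.linalg.inv(C)
        assert np.isclose(1.0 / S[0, 0], p.E_circumferential_MPa, rtol=1e-10)

    def test_strain_energy_invariant_under_rotation(self):
        rng = np.random.default_rng(3)
        p = MeniscusParams()
        C, _ = meniscus_elasticity_tensor(p, np.array([1.0, 0, 0]))
        eps = rng.normal(size=6)
        for _ in range(5):
            R = random_rotation(rng)
            Cr = rotate_voigt_stiffness(C, R)
            # rotate the strain consistently (Voigt engineering shears)
            e = np.array([[eps[0], eps[5] / 2, eps[4] / 2],
                          [eps[5] / 2, eps[1], eps[3] / 2],
                          [eps[4] / 2, eps[3] / 2, eps[2]]])
            er = R @ e @ R.T
            eps_r = np.array([er[0, 0], er[1, 1], er[2, 2],
                              2 * er[1, 2], 2 * er[0, 2], 2 * er[0, 1]])
            w0 = eps @ C @ eps
            wr = eps_r @ Cr @ eps_r
            assert np.isclose(w0, wr, rtol=1e-10)

    def test_non_physical_poisson_combination_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            MeniscusParams(nu_in_plane=0.99, nu_out_of_plane=0.9)
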