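"""Solid mechanics: strain/stress oracles, internal-force gradient check,
Newmark dynamics (cantilever frequency, patch test, energy)."""

import math

import numpy as np
import pytest

from ifem2d.cases import spectrum
from ifem2d.geometry import ConfigurationError, triangle_areas
from ifem2d.solid import (MaterialModel, NewmarkSolidSolver,
                          SolidBoundaryData, SolidState, compute_strain,
                          compute_strain_rate, constitutive_stress,
                          deformation_gradient, internal_force,
                          solid_operators, solve_solid_static,
                          update_positions)


@pytest.fixture(scope="module")
def mat():
    return MaterialModel(kind="linear-elastic", rho=1.0, E=1.0e4, nu=0.3)


def plane_strain_sigma11_oracle(E, nu, eps11):
    """σ11 for uniaxial plane strain via the full 3D isotropic Hooke law
    with ε22 = ε33 = 0 (independent of the Voigt matrix implementation)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.array([[lam + 2 * mu, lam, lam],
                  [lam, lam + 2 * mu, lam],
                  [lam, lam, lam + 2 * mu]])
    return (C @ np.array([eps11, 0.0, 0.0]))[0]


class TestStrain:
    def test_rigid_translation_is_strain_free(self, disc_lm):
        u = np.tile([0.3, -0.2], (disc_lm.n_nodes, 1))
        assert np.abs(compute_strain(disc_lm, u)).max() < 1e-12

    def test_uniaxial_stretch(self, disc_lm):
        alpha = 0.01
        u = np.column_stack([alpha * disc_lm.ref_coords[:, 0],
                             np.zeros(disc_lm.n_nodes)])
        eps = compute_strain(disc_lm, u)
        assert np.allclose(eps[:, 0], alpha, atol=1e-12)
        assert np.abs(eps[:, 1:]).max() < 1e-12

    def test_infinitesimal_rotation_is_strain_free(self, disc_lm):
        theta = 1e-3
        c = disc_lm.ref_coords
        u = theta * np.column_stack([-c[:, 1], c[:, 0]])
        assert np.abs(compute_strain(disc_lm, u)).max() < 1e-12


class TestConstitutiveStress:
    def test_zero_state_zero_stress(self, mat):
        z = np.zeros((5, 3))
        assert np.all(constitutive_stress(mat, z, z) == 0)

    def test_uniaxial_plane_strain_matches_3d_hooke_oracle(self):
        # cover-layer stiffness of the fold demo: E = 10 kPa, ν = 0.3
        E, nu, e11 = 1.0e5, 0.3, 0.01
        m = MaterialModel(E=E, nu=nu)
        eps = np.array([[e11, 0.0, 0.0]])
        sig = constitutive_stress(m, eps, np.zeros_like(eps))
        assert sig[0, 0] == pytest.approx(
            plane_strain_sigma11_oracle(E, nu, e11), rel=1e-12)
        assert sig[0, 0] == pytest.approx(
            E * (1 - nu) / ((1 + nu) * (1 - 2 * nu)) * e11, rel=1e-12)

    def test_kelvin_voigt_rate_response(self):
        m = MaterialModel(kind="viscoelastic", E=1.0, nu=0.0, eta=2.5)
        rate = 0.3
        eps = np.zeros((1, 3))
        sig = constitutive_stress(m, eps, np.array([[rate, 0.0, 0.0]]))
        assert sig[0, 0] == pytest.approx(2.5 * rate, rel=1e-12)

    def test_mooney_rivlin_unstressed_at_identity(self):
        m = MaterialModel(kind="mooney-rivlin", E=1e4, nu=0.3)
        F = np.tile(np.eye(2), (4, 1, 1))
        sig = constitutive_stress(m, None, F=F)
        assert np.abs(sig).max() < 1e-10

    def test_mooney_rivlin_small_shear_matches_linear_modulus(self):
        m = MaterialModel(kind="mooney-rivlin", E=1e4, nu=0.3)
        gamma = 1e-5
        F = np.array([[[1.0, gamma], [0.0, 1.0]]])
        sig = constitutive_stress(m, None, F=F)
        assert sig[0, 2] == pytest.approx(m.shear_modulus * gamma, rel=1e-3)

    def test_invalid_material_parameters_rejected(self):
        with pytest.raises(ValueError):
            MaterialModel(nu=0.5)
        with pytest.raises(ValueError):
            MaterialModel(rho=-1.0)
        with pytest.raises(ValueError):
            MaterialModel(kind="plastic")


class TestInternalForce:
    def test_zero_stress_zero_force(self, disc_lm):
        f = internal_force(disc_lm, np.zeros((len(disc_lm.triangles), 3)))
        assert np.all(f == 0)

    def test_single_element_uniform_stress_closed_form(self):
        """Unit right triangle under uniform σ: nodal forces equal the
        hand-integrated P1 values −A σ ∇N_a."""
        from ifem2d.geometry import LagrangianMesh
        lm = LagrangianMesh(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
                            np.array([[0, 1, 2]]), np.array([0, 1, 2]))
        sig = np.array([[2.0, -1.0, 0.5]])
        f = internal_force(lm, sig)
        # ∇N = [(-1,-1), (1,0), (0,1)], A = 1/2
        expect = -0.5 * np.array([
            [2.0 * -1 + 0.5 * -1, 0.5 * -1 + -1.0 * -1],
            [2.0 * 1 + 0.5 * 0, 0.5 * 1 + -1.0 * 0],
            [2.0 * 0 + 0.5 * 1, 0.5 * 0 + -1.0 * 1]])
        assert np.allclose(f, expect, atol=1e-14)

    def test_matches_energy_gradient(self, disc_lm, mat, rng):
        u0 = 1e-3 * rng.normal(size=(disc_lm.n_nodes, 2))
        D = mat.stiffness_voigt()
        A = triangle_areas(disc_lm.ref_coords, disc_lm.triangles)

        def energy(u):
            e = compute_strain(disc_lm, u)
            return 0.5 * np.sum(A * np.einsum("mi,ij,mj->m", e, D, e))

        f = internal_force(disc_lm, constitutive_stress(
            mat, compute_strain(disc_lm, u0)))
        h = 1e-6
        for i in (0, 3, 11):
            for j in (0, 1):
                up, um = u0.copy(), u0.copy()
                up[i, j] += h
                um[i, j] -= h
                g = (energy(up) - energy(um)) / (2 * h)
                assert -g == pytest.approx(f[i, j], rel=1e-5, abs=1e-8)

    def test_momentum_conservation(self, disc_lm, mat, rng):
        u0 = 1e-3 * rng.normal(size=(disc_lm.n_nodes, 2))
        sig = constitutive_stress(mat, compute_strain(disc_lm, u0))
        f = internal_force(disc_lm, sig)
        assert np.abs(f.sum(axis=0)).max() < 1e-10 * np.abs(f).max()


def left_edge(lm):
    return np.where(np.abs(lm.ref_coords[:, 0]) < 1e-12)[0]


def right_edge(lm, L=1.0):
    return np.where(np.abs(lm.ref_coords[:, 0] - L) < 1e-12)[0]


class TestDynamics:
    def test_rest_state_stays_at_rest(self, bar_lm, mat):
        solver = NewmarkSolidSolver(bar_lm, mat)
        st = SolidState.zero(bar_lm.n_nodes)
        bc = SolidBoundaryData(q_nodes=left_edge(bar_lm),
                               q=np.zeros((len(left_edge(bar_lm)), 2)))
        for _ in range(5):
            st = solver.step(st, bc, 1e-3)
        assert np.abs(st.u).max() < 1e-14

    def test_cantilever_axial_frequency_matches_bar_closed_form(self, bar_lm):
        """Fixed-free bar in axial vibration: f1 = (1/4L)·√(E/ρ) with
        ν = 0 (no lateral coupling)."""
        m = MaterialModel(E=1e4, nu=0.0, rho=1.0)
        solver = NewmarkSolidSolver(bar_lm, m)
        L, f1_exact = 1.0, 0.25 * math.sqrt(1e4 / 1.0) / 1.0
        st = SolidState.zero(bar_lm.n_nodes)
        st.u = np.column_stack([1e-3 * bar_lm.ref_coords[:, 0],
                                np.zeros(bar_lm.n_nodes)])
        fixed = left_edge(bar_lm)
        bc = SolidBoundaryData(q_nodes=fixed, q=np.zeros((len(fixed), 2)))
        dt = 1.0 / (f1_exact * 60)
        tip = right_edge(bar_lm)[0]
        series = []
        for _ in range(360):
            st = solver.step(st, bc, dt)
            series.append(st.u[tip, 0])
        f1 = spectrum(series, dt)
        assert f1 == pytest.approx(f1_exact, rel=0.05)

    def test_static_patch_test_uniform_traction(self, bar_lm):
        """Uniform traction on the free end with axially constrained root
        reproduces the uniform stress state exactly."""
        m = MaterialModel(E=1e4, nu=0.3)
        h = 100.0
        loop = bar_lm.boundary_loop
        segs = []
        re = set(right_edge(bar_lm).tolist())
        for a, b in zip(loop, np.roll(loop, -1)):
            if int(a) in re and int(b) in re:
                segs.append((a, b))
        bc = SolidBoundaryData(h_segments=np.array(segs),
                               h_values=np.tile([h, 0.0], (len(segs), 1)))
        fixed = list(left_edge(bar_lm)) + [int(left_edge(bar_lm)[0]) + bar_lm.n_nodes]
        u = solve_solid_static(bar_lm, m, bc, fixed_dofs=fixed)
        sig = constitutive_stress(m, compute_strain(bar_lm, u))
        assert np.abs(sig[:, 0] - h).max() / h < 1e-10
        assert np.abs(sig[:, 1]).max() / h < 1e-10
        assert np.abs(sig[:, 2]).max() / h < 1e-10

    def test_undamped_free_vibration_conserves_energy(self, bar_lm):
        """Trapezoidal Newmark conserves the discrete energy of a linear
        undamped system (drift at round-off scale over 100 steps)."""
        m = MaterialModel(E=1e4, nu=0.0, rho=1.0, eta=0.0)
        solver = NewmarkSolidSolver(bar_lm, m)
        K, ML, _ = solid_operators(bar_lm, m)
        st = SolidState.zero(bar_lm.n_nodes)
        st.u = np.column_stack([1e-3 * bar_lm.ref_coords[:, 0],
                                np.zeros(bar_lm.n_nodes)])
        fixed = left_edge(bar_lm)
        bc = SolidBoundaryData(q_nodes=fixed, q=np.zeros((len(fixed), 2)))
        st.a = solver.consistent_acceleration(st, bc)

        def energy(s):
            u = np.concatenate([s.u[:, 0], s.u[:, 1]])
            v = np.concatenate([s.v[:, 0], s.v[:, 1]])
            return 0.5 * (u @ (K @ u) + v @ (ML * v))

        e0 = energy(st)
        dt = 2e-4
        series = []
        for _ in range(100):
            st = solver.step(st, bc, dt)
            series.append(energy(st))
        assert abs(series[-1] - e0) / e0 < 1e-10

    def test_viscous_damping_dissipates_energy(self, bar_lm):
        m = MaterialModel(kind="viscoelastic", E=1e4, nu=0.0, rho=1.0, eta=5.0)
        solver = NewmarkSolidSolver(bar_lm, m)
        K, ML, _ = solid_operators(bar_lm, m)
        st = SolidState.zero(bar_lm.n_nodes)
        st.u = np.column_stack([1e-3 * bar_lm.ref_coords[:, 0],
                                np.zeros(bar_lm.n_nodes)])
        fixed = left_edge(bar_lm)
        bc = SolidBoundaryData(q_nodes=fixed, q=np.zeros((len(fixed), 2)))
        st.a = solver.consistent_acceleration(st, bc)

        def energy(s):
            u = np.concatenate([s.u[:, 0], s.u[:, 1]])
            v = np.concatenate([s.v[:, 0], s.v[:, 1]])
            return 0.5 * (u @ (K @ u) + v @ (ML * v))

        e0 = energy(st)
        for _ in range(300):
            st = solver.step(st, bc, 5e-4)
        assert energy(st) < 0.5 * e0


class TestUpdatePositions:
    def test_zero_velocity_leaves_positions(self, disc_lm):
        lm = type(disc_lm)(disc_lm.ref_coords.copy(), disc_lm.triangles.copy(),
                           disc_lm.boundary_loop.copy())
        st = SolidState.zero(lm.n_nodes)
        update_positions(lm, st, 0.1)
        assert np.array_equal(lm.cur_coords, lm.ref_coords)

    def test_uniform_velocity_shifts_everything(self, disc_lm):
        lm = type(disc_lm)(disc_lm.ref_coords.copy(), disc_lm.triangles.copy(),
                           disc_lm.boundary_loop.copy())
        st = SolidState.zero(lm.n_nodes)
        st.v = np.tile([1.0, 0.0], (lm.n_nodes, 1))
        update_positions(lm, st, 0.1)
        assert np.allclose(lm.cur_coords - lm.ref_coords, [0.1, 0.0])

    def test_two_half_steps_equal_one_full_step(self, disc_lm, rng):
        v = rng.normal(size=(disc_lm.n_nodes, 2))
        mk = lambda: type(disc_lm)(disc_lm.ref_coords.copy(),
                                   disc_lm.triangles.copy(),
                                   disc_lm.boundary_loop.copy())
        lm1, lm2 = mk(), mk()
        s1, s2 = SolidState.zero(disc_lm.n_nodes), SolidState.zero(disc_lm.n_nodes)
        s1.v = v.copy()
        s2.v = v.copy()
        update_positions(lm1, s1, 0.2)
        update_positions(lm2, s2, 0.1)
        update_positions(lm2, s2, 0.1)
        assert np.allclose(lm1.cur_coords, lm2.cur_coords, atol=1e-14)


class TestDeformationGradient:
    def test_identity_for_undeformed(self, disc_lm):
        F = deformation_gradient(disc_lm, np.zeros((disc_lm.n_nodes, 2)))
        assert np.allclose(F, np.eye(2), atol=1e-14)

    def test_strain_rate_of_linear_velocity_field(self, disc_lm):
        v = np.column_stack([0.2 * disc_lm.ref_coords[:, 1],
                             np.zeros(disc_lm.n_nodes)])
        r = compute_strain_rate(disc_lm, v)
        assert np.allclose(r[:, 2], 0.2, atol=1e-12)
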