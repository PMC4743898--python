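"""Coupling layer: indicator field, interaction-force definitions and
identities, diagnostic ratios, and orchestrator behavior."""

import math
import warnings

import numpy as np
import pytest

from ifem2d.coupling import (Body, Simulation, correction_force,
                             coupling_error_estimate, fsi_force_explicit,
                             fsi_force_modified, fsi_force_semi_implicit,
                             _fluid_convective_at_solid, solve_indicator,
                             spread_interface_normals, step_ifem)
from ifem2d.fluid import FluidBCs, FluidProperties, FluidState
from ifem2d.geometry import (ConfigurationError, generate_channel_mesh,
                             generate_disc_mesh)
from ifem2d.kernels import build_kernel, interpolate_to_solid
from ifem2d.solid import MaterialModel, internal_force


class TestSpreadInterfaceNormals:
    def test_closed_boundary_sums_to_zero(self, square_em, disc_lm):
        G = spread_interface_normals(square_em, disc_lm)
        assert np.abs(G.sum(axis=0)).max() < 1e-10

    def test_far_nodes_receive_exactly_zero(self, square_em, disc_lm):
        G = spread_interface_normals(square_em, disc_lm)
        far = np.linalg.norm(square_em.node_coords - [1.0, 1.0], axis=1) > 0.8
        assert np.all(G[far] == 0.0)

    def test_segment_contributions_carry_normal_times_length(self, square_em, disc_lm):
        """Partition of unity turns each boundary segment's spread weight
        into exactly n·L; the total |G| is bounded by the perimeter."""
        n, L = disc_lm.boundary_normals()
        G = spread_interface_normals(square_em, disc_lm)
        # each segment contributes n_q L_q in total; summing the absolute
        # row sums can only lose by cancellation
        assert np.abs(G).sum() <= np.abs(n * L[:, None]).sum() + 1e-12


@pytest.fixture(scope="module")
def I(square_em, disc_lm):
    return solve_indicator(square_em, disc_lm)


class TestIndicator:
    def test_far_fluid_nodes_are_zero(self, square_em, I):
        far = np.linalg.norm(square_em.node_coords - [1.0, 1.0], axis=1) > 0.8
        assert np.abs(I[far]).max() < 1e-12

    def test_deep_solid_nodes_are_one(self, square_em, I):
        deep = np.linalg.norm(square_em.node_coords - [1.0, 1.0], axis=1) < 0.2
        assert np.abs(I[deep] - 1.0).max() < 1e-12

    def test_bounded_between_zero_and_one(self, I):
        assert I.min() >= 0.0 and I.max() <= 1.0

    def test_integrates_to_solid_area(self, square_em, disc_lm, I):
        area = float((square_em.lumped_areas() * I).sum())
        assert area == pytest.approx(math.pi * 0.4**2, rel=0.05)

    def test_no_clamped_nodes_is_a_configuration_error(self, disc_lm):
        tiny = generate_channel_mesh(2.0, 2.0, 1.0)   # 9 nodes, all near solid
        with pytest.raises(ConfigurationError):
            solve_indicator(tiny, disc_lm, band=5.0)


@pytest.fixture
def random_force_state(square_em, disc_lm, rng):
    """Random-but-consistent inputs shared by the force-identity tests."""
    sig_s = rng.normal(size=(len(disc_lm.triangles), 3))
    div_f = rng.normal(size=(disc_lm.n_nodes, 2))
    accel = rng.normal(size=(disc_lm.n_nodes, 2))
    return sig_s, div_f, accel


class TestForceDefinitions:
    def test_explicit_vanishes_for_matched_properties(self, disc_lm, rng):
        """ρˢ = ρᶠ and σˢ-derived force equal to the fluid's: all three
        terms of the explicit interaction force cancel for any gravity."""
        mat = MaterialModel(rho=1.0)
        sig_s = rng.normal(size=(len(disc_lm.triangles), 3))
        div_f = internal_force(disc_lm, sig_s)    # σᶠ matches σˢ
        accel = rng.normal(size=(disc_lm.n_nodes, 2))
        f = fsi_force_explicit(disc_lm, mat, rho_f=1.0, accel=accel,
                               sigma_s=sig_s, div_sigma_f_force=div_f,
                               g=(0.0, -980.0))
        assert np.abs(f).max() < 1e-12 * max(1.0, np.abs(div_f).max())

    def test_explicit_gravity_term_is_lumped_buoyant_weight(self, disc_lm):
        mat = MaterialModel(rho=2.0)
        z3 = np.zeros((len(disc_lm.triangles), 3))
        z2 = np.zeros((disc_lm.n_nodes, 2))
        f = fsi_force_explicit(disc_lm, mat, rho_f=0.5, accel=z2,
                               sigma_s=z3, div_sigma_f_force=z2,
                               g=(0.0, -980.0))
        expect = (2.0 - 0.5) * disc_lm.lumped_areas() * -980.0
        assert np.allclose(f[:, 1], expect, rtol=1e-12)
        assert np.abs(f[:, 0]).max() == 0.0

    def test_explicit_reduces_to_internal_force_for_stretched_block(self, disc_lm, rng):
        """Quiescent fluid, ρˢ = ρᶠ, no gravity: only ∇·σˢ remains."""
        mat = MaterialModel(rho=1.0)
        sig_s = rng.normal(size=(len(disc_lm.triangles), 3))
        z2 = np.zeros((disc_lm.n_nodes, 2))
        f = fsi_force_explicit(disc_lm, mat, 1.0, z2, sig_s, z2)
        assert np.allclose(f, internal_force(disc_lm, sig_s), atol=1e-14)

    def test_semi_implicit_drops_inertia_and_gravity(self, disc_lm, random_force_state):
        sig_s, div_f, _ = random_force_state
        f = fsi_force_semi_implicit(disc_lm, sig_s, div_f)
        assert np.allclose(f, internal_force(disc_lm, sig_s) - div_f, atol=1e-14)

    def test_semi_implicit_equals_explicit_when_densities_match(
            self, disc_lm, random_force_state):
        sig_s, div_f, _ = random_force_state
        mat = MaterialModel(rho=1.0)
        accel = np.random.default_rng(5).normal(size=(disc_lm.n_nodes, 2))
        fe = fsi_force_explicit(disc_lm, mat, 1.0, accel, sig_s, div_f,
                                g=(0.0, 0.0))
        fs = fsi_force_semi_implicit(disc_lm, sig_s, div_f)
        assert np.abs(fe - fs).max() < 1e-12 * np.abs(fs).max()

    def test_modified_is_semi_implicit_plus_weighted_correction(
            self, disc_lm, random_force_state, rng):
        sig_s, div_f, _ = random_force_state
        fdv = rng.normal(size=(disc_lm.n_nodes, 2))
        fm = fsi_force_modified(disc_lm, sig_s, div_f, fdv)
        expect = (fsi_force_semi_implicit(disc_lm, sig_s, div_f)
                  + disc_lm.lumped_areas()[:, None] * fdv)
        assert np.abs(fm - expect).max() < 1e-12 * np.abs(expect).max()

    def test_correction_zero_for_matching_material_derivatives(self, rng):
        a = rng.normal(size=(40, 2))
        assert np.all(correction_force(1000.0, a, a) == 0.0)

    def test_correction_for_accelerating_solid_in_quiescent_fluid(self):
        a = np.tile([3.0, -1.0], (10, 1))
        f = correction_force(2.0, a, np.zeros_like(a))
        assert np.allclose(f, 2.0 * a)

    def test_convective_term_matches_analytic_gradient(self, square_em, disc_lm):
        """vᶠ = (y, 0): (v·∇)v = (y·0 + 0·1, 0) = 0; vᶠ = (x, -y):
        (v·∇)v = (x, y).  Checked through the nodal-average pipeline."""
        k = build_kernel(square_em, disc_lm)
        c = square_em.node_coords
        st = FluidState(np.column_stack([c[:, 0], -c[:, 1]]), np.zeros(len(c)))
        conv = _fluid_convective_at_solid(square_em, k, st)
        pts = disc_lm.cur_coords
        expect = np.column_stack([pts[:, 0], pts[:, 1]])
        # interior nodal averaging is exact for linear fields away from
        # the domain boundary
        assert np.abs(conv - expect).max() < 1e-9


class TestCouplingErrorEstimate:
    def test_matched_densities_zero_ratios(self):
        d = coupling_error_estimate(1.0, 1.0, K=5e3, g=(0, 0))
        assert d["density_ratio"] == 0.0
        assert d["gravity_ratio"] == 0.0

    def test_thousandfold_density_ratio(self):
        d = coupling_error_estimate(1.0, 1e-3, K=1e4)
        assert d["density_ratio"] == pytest.approx(999.0)

    def test_semi_implicit_stiffness_ratio_smaller_for_heavy_solid(self):
        d = coupling_error_estimate(2.0, 1e-3, K=1e4, dt=1e-4)
        assert d["stiffness_ratio_semi_implicit"] < d["stiffness_ratio_explicit"]
        assert d["predicted_error_scale"] > 0


class TestOrchestrators:
    def _sim(self, algorithm, rho_s=1.0, g=(0.0, 0.0)):
        em = generate_channel_mesh(2.0, 1.0, 0.125)
        props = FluidProperties(rho=1.0, mu=0.05, g=g)
        bcs = FluidBCs(dirichlet={"inlet": (0.5, 0.0), "wall": (0.0, 0.0)},
                       outflow=("outlet",))
        lm = generate_disc_mesh((0.6, 0.5), 0.15, 0.15 / 3)
        mat = MaterialModel(kind="viscoelastic", rho=rho_s, E=500.0,
                            nu=0.45, eta=0.05)
        return Simulation(em, props, bcs, [Body(lm, mat)], dt=2e-4,
                          algorithm=algorithm, max_iter=30, tol=1e-7)

    def test_explicit_and_semi_implicit_agree_at_first_step(self):
        """With ρˢ = ρᶠ and g = 0 the two force definitions coincide
        term by term, so the first fluid solve sees identical forcing."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = self._sim("ifem")
            s2 = self._sim("semi_implicit")
            s1.step()
            s2.step()
        assert np.allclose(s1.fluid.v, s2.fluid.v, atol=1e-9)

    def test_conservation_residual_logged_every_step(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = self._sim("ifem")
            for _ in range(3):
                sim.step()
        for entry in sim.log:
            assert entry["conservation_residual"] < 1e-10 * max(
                1.0, abs(entry["div_norm"]))
            assert np.isfinite(entry["min_solid_area"])

    def test_invalid_algorithm_and_dt_rejected(self):
        em = generate_channel_mesh(1.0, 1.0, 0.25)
        props = FluidProperties()
        bcs = FluidBCs(dirichlet={"wall": (0, 0), "inlet": (0, 0),
                                  "outlet": (0, 0)})
        with pytest.raises(ConfigurationError):
            Simulation(em, props, bcs, [], dt=-1.0)
        with pytest.raises(ConfigurationError):
            Simulation(em, props, bcs, [], dt=0.1, algorithm="monolithic")

    def test_solid_velocity_is_fluid_interpolant_in_explicit_scheme(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = self._sim("ifem")
            sim.step()
        b = sim.bodies[0]
        # kernel was rebuilt after motion; rebuild the pre-motion one
        lm_check = b.lm
        prev = lm_check.cur_coords - b.state.v * sim.dt
        k = build_kernel(sim.em, prev)
        assert np.allclose(interpolate_to_solid(k, sim.fluid.v), b.state.v,
                           atol=1e-12)

    def test_mifem_solid_velocity_not_overwritten_by_fluid(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = self._sim("mifem")
            for _ in range(3):
                sim.step()
        b = sim.bodies[0]
        vf = interpolate_to_solid(b.kernel, sim.fluid.v)
        # the solid has its own dynamics: the velocities track the fluid
        # but are not identical to the interpolant
        assert not np.allclose(vf, b.state.v, atol=1e-14)
        assert np.isfinite(b.state.v).all()
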