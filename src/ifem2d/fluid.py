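"""Stabilized equal-order (P1/P1) finite element solver for the
incompressible — and, in the artificial-solid region, pseudo-compressible —
Navier–Stokes equations on the fixed Eulerian mesh.

Momentum:    ρ (∂v/∂t + v·∇v) = ∇·σᶠ + ρ g + fᶠˢⁱ,   σᶠ = −p I + µ(∇v + ∇vᵀ)
Continuity:  ∇·v = 0, or  (1/κˢ)(∂p/∂t) I(x) + ∇·v = 0  in pseudo-compressible
             mode, where I is the solid indicator and κˢ the solid bulk
             compressibility.

The density ρ may be a constant (the physical fluid) or a nodal field
(the effective density ρ̄ = ρf + (ρs − ρf)·I of the semi-implicit scheme).
Passing a ρ̄ field that is everywhere equal to ρf assembles exactly the
same discrete operators as the constant-density form — the semi-implicit
momentum equation degenerates to the original one.

Discretization: linear triangles for both velocity and pressure with
SUPG/PSPG residual stabilization (the standard remedy for the equal-order
pair), backward-Euler time stepping, and Picard linearization of the
convective term.  The element stabilization parameter is

    τ_e = [ (2 ρ̄_e / Δt)² + (2 ρ̄_e |v*| / h_e)² + (12 µ / h_e²)² ]^(-1/2)

with h_e = sqrt(2 A_e); the Δt term is dropped for steady solves.  FSI
forces enter the discrete momentum equations as nodal forces distributed
by the coupling kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import EulerianMesh

__all__ = [
    "FluidProperties", "FluidState", "FluidBCs", "StabilizedFluidSolver",
    "SolverDivergenceError", "solve_fluid_step", "effective_density",
    "fluid_stress", "fluid_stress_divergence", "divergence_norm",
]


class SolverDivergenceError(RuntimeError):
    """Picard iteration failed to converge; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass
class FluidProperties:
    """Newtonian fluid: density ρf (g/cm³), dynamic viscosity µ (g/cm·s)
    and body acceleration g (cm/s²)."""

    rho: float = 1.0
    mu: float = 0.01
    g: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("fluid density and viscosity must be positive")


@dataclass
class FluidState:
    """Nodal velocity (cm/s), nodal pressure (dyn/cm²) and time (s)."""

    v: np.ndarray
    p: np.ndarray
    t: float = 0.0

    @classmethod
    def zero(cls, n_nodes: int) -> "FluidState":
        return cls(np.zeros((n_nodes, 2)), np.zeros(n_nodes), 0.0)

    def copy(self) -> "FluidState":
        return FluidState(self.v.copy(), self.p.copy(), self.t)


@dataclass
class FluidBCs:
    """Boundary conditions by mesh tag.

    dirichlet : tag -> (vx, vy) constant, or callable(coords) -> (n, 2)
    traction  : tag -> imposed boundary pressure p̄ (traction t = −p̄ n)
    outflow   : tags with the natural (zero-traction) condition
    gauge_node: node whose pressure is pinned to zero; set automatically
        when no traction/outflow boundary fixes the pressure level
    """

    dirichlet: dict = field(default_factory=dict)
    traction: dict = field(default_factory=dict)
    outflow: tuple = ()
    gauge_node: int | None = None


def effective_density(indicator: np.ndarray, rho_f: float, rho_s: float) -> np.ndarray:
    """Nodal effective density ρ̄ = ρf + (ρs − ρf)·I.

    I identifies the real-fluid (I=0) and solid (I=1) regions; values must
    lie in [0, 1]."""
    I = np.asarray(indicator, dtype=float)
    if I.min() < -1e-9 or I.max() > 1.0 + 1e-9:
        raise ValueError("indicator field out of [0, 1]")
    return rho_f + (rho_s - rho_f) * np.clip(I, 0.0, 1.0)


# quadrature: edge-midpoint rule, exact for quadratics on a triangle
_QN = np.array([[0.0, 0.5, 0.5],
                [0.5, 0.0, 0.5],
                [0.5, 0.5, 0.0]])


def _element_gradients(em: EulerianMesh):
    """Constant P1 shape gradients b (M, 3, 2) and areas (M,)."""
    c = em.node_coords[em.triangles]          # (M, 3, 2)
    p0, p1, p2 = c[:, 0], c[:, 1], c[:, 2]
    d1, d2 = p1 - p0, p2 - p0
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]   # 2 A
    A = 0.5 * det
    b = np.empty((len(A), 3, 2))
    b[:, 0, 0] = p1[:, 1] - p2[:, 1]
    b[:, 0, 1] = p2[:, 0] - p1[:, 0]
    b[:, 1, 0] = p2[:, 1] - p0[:, 1]
    b[:, 1, 1] = p0[:, 0] - p2[:, 0]
    b[:, 2, 0] = p0[:, 1] - p1[:, 1]
    b[:, 2, 1] = p1[:, 0] - p0[:, 0]
    b /= det[:, None, None]
    return b, A


def fluid_stress(em: EulerianMesh, state: FluidState, props: FluidProperties) -> np.ndarray:
    """Per-element Cauchy stress σᶠ = −p I + µ(∇v + ∇vᵀ), with the
    element-constant velocity gradient and centroid pressure."""
    b, _ = _element_gradients(em)
    ve = state.v[em.triangles]                     # (M, 3, 2)
    grad = np.einsum("mai,maj->mij", ve, b)        # grad[i,j] = dv_i/dx_j
    pbar = state.p[em.triangles].mean(axis=1)
    sig = props.mu * (grad + grad.transpose(0, 2, 1))
    sig[:, 0, 0] -= pbar
    sig[:, 1, 1] -= pbar
    return sig


def fluid_stress_divergence(em: EulerianMesh, state: FluidState,
                            props: FluidProperties) -> np.ndarray:
    """Weak-form nodal forces of ∇·σᶠ on the fluid mesh:
    r[a] = −Σ_e A_e σ_e · ∇N_a (the Galerkin residual of the stress term)."""
    b, A = _element_gradients(em)
    sig = fluid_stress(em, state, props)
    fe = -np.einsum("m,mij,maj->mai", A, sig, b)   # (M, 3, 2)
    out = np.zeros((em.n_nodes, 2))
    np.add.at(out, em.triangles.ravel(), fe.reshape(-1, 2))
    return out


def divergence_norm(em: EulerianMesh, state: FluidState) -> float:
    """L² norm of the element-wise discrete divergence of the velocity."""
    b, A = _element_gradients(em)
    ve = state.v[em.triangles]
    div = np.einsum("mai,mai->m", ve, b)
    return float(np.sqrt(np.sum(A * div * div)))


class StabilizedFluidSolver:
    """Assembles and solves one implicit (backward-Euler) step of the
    stabilized weak form.  Element geometry is precomputed once — the
    Eulerian mesh never moves."""

    def __init__(self, em: EulerianMesh, props: FluidProperties, bcs: FluidBCs,
                 max_iter: int = 20, tol: float = 1e-8, relax: float = 1.0):
        self.em = em
        self.props = props
        self.bcs = bcs
        self.max_iter = max_iter
        self.tol = tol
        self.relax = relax    # Picard under-relaxation of the iterate
        self.b, self.A_e = _element_gradients(em)
        self.h_e = np.sqrt(2.0 * self.A_e)
        self.n = em.n_nodes
        self.lumped = em.lumped_areas()
        self._prep_bcs()
        tpl = em.triangles
        # scatter pattern for the 9x9 local blocks: [ux0..2, uy0..2, p0..2]
        self.loc = np.concatenate([tpl, tpl + self.n, tpl + 2 * self.n], axis=1)
        self.rows = np.repeat(self.loc, 9, axis=1).ravel()
        self.cols = np.tile(self.loc, (1, 9)).ravel()

    # -- boundary conditions ------------------------------------------------
    def _prep_bcs(self):
        em, bcs = self.em, self.bcs
        dval = np.zeros((self.n, 2))
        dmask = np.zeros(self.n, dtype=bool)
        for tag, val in bcs.dirichlet.items():
            nodes = em.boundary_tags[tag]
            if callable(val):
                dval[nodes] = np.asarray(val(em.node_coords[nodes]), dtype=float)
            else:
                dval[nodes] = np.asarray(val, dtype=float)
            dmask[nodes] = True
        self.dmask, self.dval = dmask, dval

        # geometric traction factors ∫ N_a n dΓ per tagged boundary; the
        # imposed pressure (a constant or a callable of time) multiplies
        # them at assembly, so ramped inlet pressures cost nothing extra
        self.trac_geom: dict[str, np.ndarray] = {}
        if bcs.traction:
            edges = em.boundary_edges()
            for tag in bcs.traction:
                geom = np.zeros((self.n, 2))
                s = set(em.boundary_tags[tag].tolist())
                for e in edges:
                    if int(e[0]) in s and int(e[1]) in s:
                        d = em.node_coords[e[1]] - em.node_coords[e[0]]
                        nvec = np.array([d[1], -d[0]])  # outward, |n|=len
                        geom[e[0]] += 0.5 * nvec
                        geom[e[1]] += 0.5 * nvec
                self.trac_geom[tag] = geom

        has_pressure_bc = bool(bcs.traction) or bool(bcs.outflow)
        self.gauge = bcs.gauge_node
        if self.gauge is None and not has_pressure_bc:
            self.gauge = 0

    # -- assembly -----------------------------------------------------------
    def assemble(self, v_star: np.ndarray, state_prev: FluidState,
                 rho_nodal: np.ndarray | None = None,
                 fsi_force: np.ndarray | None = None,
                 mode: str = "incompressible",
                 kappa: float | None = None,
                 indicator: np.ndarray | None = None,
                 dt: float | None = None,
                 steady: bool = False):
        """Assemble the linearized system about the convective iterate
        ``v_star``.  Returns (A, rhs) before Dirichlet/gauge rows are set."""
        em, props = self.em, self.props
        tpl = em.triangles
        M, n = len(tpl), self.n
        mu = props.mu
        g = np.asarray(props.g, dtype=float)
        rho = (np.full(n, props.rho) if rho_nodal is None
               else np.asarray(rho_nodal, dtype=float))

        b, A_e = self.b, self.A_e
        h = self.h_e
        re = rho[tpl]                               # (M, 3)
        ve = v_star[tpl]                            # (M, 3, 2)
        vne = state_prev.v[tpl]
        wq = A_e / 3.0                              # midpoint-rule weights

        rho_q = np.einsum("qa,ma->mq", _QN, re)     # ρ at quad points
        vq = np.einsum("qa,mai->mqi", _QN, ve)
        vnq = np.einsum("qa,mai->mqi", _QN, vne)
        adv = np.einsum("mqi,mbi->mqb", vq, b)      # v*·∇N_b at quad points

        rbar = re.mean(axis=1)
        vmag = np.linalg.norm(ve.mean(axis=1), axis=1)
        inv2 = (2.0 * rbar * vmag / h) ** 2 + (12.0 * mu / h**2) ** 2
        if not steady:
            inv2 = inv2 + (2.0 * rbar / dt) ** 2
        tau = 1.0 / np.sqrt(inv2)

        K = np.zeros((M, 9, 9))
        F = np.zeros((M, 9))

        for q in range(3):
            Nq = _QN[q]
            w = wq * rho_q[:, q]                    # ∫-weight × ρ at q
            advq = adv[:, q]                        # (M, 3)

            # Galerkin convection (+ mass) on both velocity components
            blk = np.einsum("m,a,mb->mab", w, Nq, advq)
            if not steady:
                blk = blk + np.einsum("m,a,b->mab", w / dt, Nq, Nq)
                F[:, 0:3] += np.einsum("m,a->ma", w / dt * vnq[:, q, 0], Nq)
                F[:, 3:6] += np.einsum("m,a->ma", w / dt * vnq[:, q, 1], Nq)
            K[:, 0:3, 0:3] += blk
            K[:, 3:6, 3:6] += blk
            F[:, 0:3] += np.einsum("m,a->ma", w * g[0], Nq)
            F[:, 3:6] += np.einsum("m,a->ma", w * g[1], Nq)

            # SUPG: test weight τ ρ (v*·∇N_a) against the momentum residual
            wa = tau[:, None] * rho_q[:, q, None] * advq        # (M, 3)
            sblk = np.einsum("ma,m,mb->mab", wa, w, advq)
            if not steady:
                sblk = sblk + np.einsum("ma,m,b->mab", wa, w / dt, Nq)
                F[:, 0:3] += wa * (w / dt * vnq[:, q, 0])[:, None]
                F[:, 3:6] += wa * (w / dt * vnq[:, q, 1])[:, None]
            K[:, 0:3, 0:3] += sblk
            K[:, 3:6, 3:6] += sblk
            K[:, 0:3, 6:9] += np.einsum("ma,m,mb->mab", wa, wq, b[:, :, 0])
            K[:, 3:6, 6:9] += np.einsum("ma,m,mb->mab", wa, wq, b[:, :, 1])
            F[:, 0:3] += wa * (w * g[0])[:, None]
            F[:, 3:6] += wa * (w * g[1])[:, None]

            # PSPG: test weight τ ∇N_a against the momentum residual
            tw = tau * wq * rho_q[:, q]
            K[:, 6:9, 0:3] += np.einsum("m,ma,mb->mab", tw, b[:, :, 0], advq)
            K[:, 6:9, 3:6] += np.einsum("m,ma,mb->mab", tw, b[:, :, 1], advq)
            if not steady:
                K[:, 6:9, 0:3] += np.einsum("m,ma,b->mab", tw / dt, b[:, :, 0], Nq)
                K[:, 6:9, 3:6] += np.einsum("m,ma,b->mab", tw / dt, b[:, :, 1], Nq)
                F[:, 6:9] += np.einsum("m,ma->ma", tw / dt * vnq[:, q, 0], b[:, :, 0])
                F[:, 6:9] += np.einsum("m,ma->ma", tw / dt * vnq[:, q, 1], b[:, :, 1])
            F[:, 6:9] += (np.einsum("m,ma->ma", tw * g[0], b[:, :, 0])
                          + np.einsum("m,ma->ma", tw * g[1], b[:, :, 1]))

        # exact (element-constant) terms.  The viscous term uses the
        # gradient ("do-nothing") form µ∫∇w:∇v — equivalent to the stress
        # form for divergence-free fields, and its natural boundary
        # condition −p n + µ ∂v/∂n = 0 is exact for fully developed
        # channel flow at open boundaries.
        dot = np.einsum("mai,mbi->mab", b, b)
        visc = mu * A_e[:, None, None] * dot
        K[:, 0:3, 0:3] += visc
        K[:, 3:6, 3:6] += visc
        # pressure gradient −(∇·w, p) and Galerkin continuity (q, ∇·v)
        K[:, 0:3, 6:9] -= np.einsum("ma,b->mab", wq[:, None] * b[:, :, 0], np.ones(3))
        K[:, 3:6, 6:9] -= np.einsum("ma,b->mab", wq[:, None] * b[:, :, 1], np.ones(3))
        K[:, 6:9, 0:3] += np.einsum("a,mb->mab", np.ones(3), wq[:, None] * b[:, :, 0])
        K[:, 6:9, 3:6] += np.einsum("a,mb->mab", np.ones(3), wq[:, None] * b[:, :, 1])
        # PSPG pressure Laplacian τ ∫ ∇N_a·∇N_b
        K[:, 6:9, 6:9] += (tau * A_e)[:, None, None] * dot

        A = sp.csr_matrix((K.ravel(), (self.rows, self.cols)),
                          shape=(3 * n, 3 * n))
        rhs = np.zeros(3 * n)
        np.add.at(rhs, self.loc.ravel(), F.ravel())

        # pseudo-compressible continuity: lumped (M_L I/(κ Δt))(p − pⁿ⁻¹)
        if mode == "pseudo-compressible":
            if kappa is None or indicator is None or steady:
                raise ValueError("pseudo-compressible mode needs kappa, indicator and dt")
            coef = self.lumped * np.clip(indicator, 0.0, 1.0) / (kappa * dt)
            A = A + sp.diags(np.concatenate([np.zeros(2 * n), coef]))
            rhs[2 * n:] += coef * state_prev.p
        elif mode != "incompressible":
            raise ValueError(f"unknown fluid mode {mode!r}")

        # nodal FSI forces and boundary tractions enter the momentum RHS
        if fsi_force is not None:
            rhs[:n] += fsi_force[:, 0]
            rhs[n:2 * n] += fsi_force[:, 1]
        t_now = state_prev.t + (0.0 if steady or dt is None else dt)
        for tag, geom in self.trac_geom.items():
            pbar = self.bcs.traction[tag]
            pval = float(pbar(t_now)) if callable(pbar) else float(pbar)
            rhs[:n] -= pval * geom[:, 0]
            rhs[n:2 * n] -= pval * geom[:, 1]
        return A, rhs

    def _apply_dirichlet(self, A, rhs):
        n = self.n
        fix = np.zeros(3 * n, dtype=bool)
        vals = np.zeros(3 * n)
        fix[:n] = self.dmask
        fix[n:2 * n] = self.dmask
        vals[:n] = self.dval[:, 0]
        vals[n:2 * n] = self.dval[:, 1]
        if self.gauge is not None:
            fix[2 * n + self.gauge] = True
        free = sp.diags((~fix).astype(float))
        A = free @ A + sp.diags(fix.astype(float))
        rhs = np.where(fix, vals, rhs)
        return A.tocsc(), rhs

    # -- one implicit step ---------------------------------------------------
    def step(self, state_prev: FluidState, dt: float | None = None,
             rho_nodal: np.ndarray | None = None,
             fsi_force: np.ndarray | None = None,
             mode: str = "incompressible", kappa: float | None = None,
             indicator: np.ndarray | None = None,
             steady: bool = False, v_init: np.ndarray | None = None):
        """Advance one backward-Euler step (or solve the steady problem).

        Returns (FluidState, info); info records the Picard history and the
        discrete divergence norm of the converged state.
        """
        if not steady and (dt is None or dt <= 0):
            raise ValueError("a positive dt is required for a transient step")
        v_star = state_prev.v.copy() if v_init is None else np.array(v_init, dtype=float)
        history: list[float] = []
        scale = max(float(np.abs(self.dval).max(initial=0.0)),
                    float(np.abs(state_prev.v).max(initial=0.0)), 1e-30)
        state = state_prev
        for _ in range(self.max_iter):
            A, rhs = self.assemble(v_star, state_prev, rho_nodal, fsi_force,
                                   mode, kappa, indicator, dt, steady)
            A, rhs = self._apply_dirichlet(A, rhs)
            sol = spla.spsolve(A, rhs)
            n = self.n
            v_new = np.column_stack([sol[:n], sol[n:2 * n]])
            p_new = sol[2 * n:]
            dv = float(np.linalg.norm(v_new - v_star)
                       / max(np.linalg.norm(v_new), scale))
            history.append(dv)
            v_star = self.relax * v_new + (1.0 - self.relax) * v_star
            state = FluidState(v_new, p_new,
                               state_prev.t + (0.0 if steady else dt))
            if not np.isfinite(dv):
                raise SolverDivergenceError(
                    "fluid iteration produced non-finite values", history)
            if dv < self.tol:
                break
        else:
            raise SolverDivergenceError(
                f"Picard iteration did not converge in {self.max_iter} steps "
                f"(last relative change {history[-1]:.3e})", history)
        info = {"picard": history, "div_norm": divergence_norm(self.em, state)}
        return state, info


def solve_fluid_step(em: EulerianMesh, state_prev: FluidState,
                     props: FluidProperties, bcs: FluidBCs,
                     dt: float | None = None, *, rho_nodal=None,
                     fsi_force=None, mode="incompressible", kappa=None,
                     indicator=None, steady=False,
                     max_iter: int = 20, tol: float = 1e-8):
    """One-shot convenience wrapper: build a solver and take one step.
    Time-stepping loops should hold a :class:`StabilizedFluidSolver`."""
    solver = StabilizedFluidSolver(em, props, bcs, max_iter=max_iter, tol=tol)
    return solver.step(state_prev, dt, rho_nodal=rho_nodal, fsi_force=fsi_force,
                       mode=mode, kappa=kappa, indicator=indicator, steady=steady)
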