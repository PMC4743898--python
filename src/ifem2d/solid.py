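"""Lagrangian solid mechanics on the moving triangle mesh.

Small-strain plane-strain kinematics with linear-elastic or Kelvin–Voigt
viscoelastic constitutive laws (σ = C:ε + η ε̇), plus a compressible
Mooney–Rivlin hyperelastic stress evaluated from the full deformation
gradient.  The dynamic equation ρˢ ü = ∇·σˢ is integrated with the
trapezoidal Newmark scheme (β = 1/4, γ = 1/2, unconditionally stable).

In the explicit/semi-implicit immersed schemes the solid equation is only
*evaluated* (strain → stress → internal force feeding the FSI force); in
the modified scheme it is *solved*, with boundary data interpolated from
the fluid: a Dirichlet displacement increment q = vᶠ Δt and/or a traction
h = −σᶠ·n on complementary parts of the boundary.

Plane strain is assumed for all 2D solids (tissue cross-sections).  The
linear kinds use the infinitesimal strain of the reference configuration;
no large-displacement co-rotation is applied — a documented validity limit
for large rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import LagrangianMesh, triangle_areas

__all__ = [
    "MaterialModel", "SolidState", "SolidBoundaryData", "StepRejectionError",
    "compute_strain", "compute_strain_rate", "constitutive_stress",
    "internal_force", "solid_operators", "solve_solid_dynamics",
    "solve_solid_static", "update_positions",
]


class StepRejectionError(RuntimeError):
    """The solid step produced an inverted element or failed to solve."""


@dataclass
class MaterialModel:
    """Solid material: density ρˢ (g/cm³), Young's modulus E (dyn/cm²),
    Poisson ratio ν, scalar Kelvin–Voigt viscosity η (g/cm·s), bulk
    compressibility κˢ (dyn/cm²; default the plane-strain bulk modulus
    E / (2(1+ν)(1−2ν))), and Mooney–Rivlin constants c1, c2 (derived from
    the shear modulus when not given)."""

    kind: str = "linear-elastic"     # linear-elastic | viscoelastic | mooney-rivlin
    rho: float = 1.0
    E: float = 1.0e4
    nu: float = 0.3
    eta: float = 0.0
    kappa: float | None = None
    c1: float | None = None
    c2: float | None = None

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("solid density must be positive")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in (-1, 0.5)")
        if self.kind not in ("linear-elastic", "viscoelastic", "mooney-rivlin"):
            raise ValueError(f"unknown material kind {self.kind!r}")
        if self.kappa is None:
            self.kappa = self.E / (2.0 * (1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        if self.kappa <= 0:
            raise ValueError("bulk compressibility must be positive")
        mu = self.shear_modulus
        if self.c1 is None:
            self.c1 = 0.4375 * mu
        if self.c2 is None:
            self.c2 = 0.0625 * mu

    @property
    def shear_modulus(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def K_equiv(self) -> float:
        """Equivalent stiffness entering the coupling-error ratios."""
        return self.E

    def stiffness_voigt(self) -> np.ndarray:
        """Plane-strain Hooke matrix for Voigt vectors [ε11, ε22, γ12]."""
        E, nu = self.E, self.nu
        f = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
        return f * np.array([
            [1.0 - nu, nu, 0.0],
            [nu, 1.0 - nu, 0.0],
            [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0],
        ])

    def viscosity_voigt(self) -> np.ndarray:
        """Kelvin–Voigt matrix: σᵛ_ij = η ε̇_ij (shear column carries the
        1/2 converting the engineering rate γ̇ = 2 ε̇12)."""
        return self.eta * np.diag([1.0, 1.0, 0.5])


@dataclass
class SolidState:
    """Nodal displacement, velocity and acceleration of the solid."""

    u: np.ndarray
    v: np.ndarray
    a: np.ndarray
    t: float = 0.0

    @classmethod
    def zero(cls, n_nodes: int) -> "SolidState":
        z = np.zeros((n_nodes, 2))
        return cls(z.copy(), z.copy(), z.copy(), 0.0)

    def copy(self) -> "SolidState":
        return SolidState(self.u.copy(), self.v.copy(), self.a.copy(), self.t)


@dataclass
class SolidBoundaryData:
    """Boundary data for the solid solve: prescribed displacement
    increments q (cm, for this step) on the nodes ``q_nodes`` and constant
    tractions h (dyn/cm²) on the segments ``h_segments``; the two sets
    live on complementary parts of the boundary."""

    q_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    q: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    h_segments: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    h_values: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def _ref_gradients(lm: LagrangianMesh):
    c = lm.ref_coords[lm.triangles]
    p0, p1, p2 = c[:, 0], c[:, 1], c[:, 2]
    d1, d2 = p1 - p0, p2 - p0
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
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


def _field_gradient(lm: LagrangianMesh, field_: np.ndarray) -> np.ndarray:
    """Element-constant gradient ∂field_i/∂X_j of a nodal vector field."""
    b, _ = _ref_gradients(lm)
    fe = field_[lm.triangles]
    return np.einsum("mai,maj->mij", fe, b)


def compute_strain(lm: LagrangianMesh, u: np.ndarray) -> np.ndarray:
    """Infinitesimal strain per element, Voigt [ε11, ε22, γ12 = 2ε12]."""
    areas = triangle_areas(lm.ref_coords + u, lm.triangles)
    if np.any(areas <= 0):
        raise StepRejectionError("inverted element in strain evaluation")
    g = _field_gradient(lm, u)
    return np.stack([g[:, 0, 0], g[:, 1, 1], g[:, 0, 1] + g[:, 1, 0]], axis=1)


def compute_strain_rate(lm: LagrangianMesh, v: np.ndarray) -> np.ndarray:
    """Strain rate per element from the nodal velocity, Voigt form."""
    g = _field_gradient(lm, v)
    return np.stack([g[:, 0, 0], g[:, 1, 1], g[:, 0, 1] + g[:, 1, 0]], axis=1)


def deformation_gradient(lm: LagrangianMesh, u: np.ndarray) -> np.ndarray:
    """F = I + ∂u/∂X per element."""
    g = _field_gradient(lm, u)
    return g + np.eye(2)[None]


def constitutive_stress(mat: MaterialModel, strain: np.ndarray,
                        strain_rate: np.ndarray | None = None,
                        F: np.ndarray | None = None) -> np.ndarray:
    """Element stress in Voigt form [σ11, σ22, σ12].

    Linear kinds: plane-strain Hooke plus the Kelvin–Voigt rate term.
    ``mooney-rivlin``: compressible Mooney–Rivlin Cauchy stress from the
    deformation gradient ``F`` (plane strain: F₃₃ = 1), with strain
    energy W = c1(Ī₁−3) + c2(Ī₂−3) + κ/2 (J−1)².
    """
    if mat.kind == "mooney-rivlin":
        if F is None:
            raise ValueError("mooney-rivlin stress needs the deformation gradient")
        F3 = np.zeros((len(F), 3, 3))
        F3[:, :2, :2] = F
        F3[:, 2, 2] = 1.0
        J = np.linalg.det(F3)
        B = F3 @ F3.transpose(0, 2, 1)
        Jm23 = J ** (-2.0 / 3.0)
        Bbar = Jm23[:, None, None] * B
        I1 = np.trace(Bbar, axis1=1, axis2=2)
        B2 = Bbar @ Bbar
        I2 = 0.5 * (I1**2 - np.trace(B2, axis1=1, axis2=2))
        eye = np.eye(3)[None]
        dev = (
            2.0 * (mat.c1 + I1[:, None, None] * mat.c2) * Bbar
            - 2.0 * mat.c2 * B2
            - (2.0 / 3.0) * (mat.c1 * I1 + 2.0 * mat.c2 * I2)[:, None, None] * eye
        ) / J[:, None, None]
        sig = dev + (mat.kappa * (J - 1.0))[:, None, None] * eye
        return np.stack([sig[:, 0, 0], sig[:, 1, 1], sig[:, 0, 1]], axis=1)

    D = mat.stiffness_voigt()
    sig = strain @ D.T
    if strain_rate is not None and mat.eta != 0.0:
        sig = sig + strain_rate @ mat.viscosity_voigt().T
    return sig


def internal_force(lm: LagrangianMesh, sigma: np.ndarray) -> np.ndarray:
    """Weak-form nodal forces of ∇·σˢ on the reference configuration:
    f[a] = −Σ_e A_e σ_e ∇N_a.  For the elastic part this equals
    −∂(strain energy)/∂u, and it sums to zero over all nodes for any
    stress state (momentum conservation of internal forces)."""
    b, A = _ref_gradients(lm)
    s11, s22, s12 = sigma[:, 0], sigma[:, 1], sigma[:, 2]
    fx = -A[:, None] * (s11[:, None] * b[:, :, 0] + s12[:, None] * b[:, :, 1])
    fy = -A[:, None] * (s12[:, None] * b[:, :, 0] + s22[:, None] * b[:, :, 1])
    out = np.zeros((lm.n_nodes, 2))
    np.add.at(out, lm.triangles.ravel(), np.stack([fx, fy], axis=2).reshape(-1, 2))
    return out


def _material_per_element(lm: LagrangianMesh, mat) -> list:
    """Expand a material or a {element_set_name: material} mapping into a
    list of (element_index_array, MaterialModel)."""
    if isinstance(mat, MaterialModel):
        return [(np.arange(len(lm.triangles)), mat)]
    out = []
    for name, m in mat.items():
        out.append((lm.element_sets[name], m))
    return out


def solid_operators(lm: LagrangianMesh, mat) -> tuple[sp.csr_matrix, np.ndarray, sp.csr_matrix]:
    """Assemble the stiffness K, lumped mass diagonal M_L and damping C of
    the solid in its reference configuration.  ``mat`` may be a single
    material or a mapping from element-set name to material (layered
    solids).  Dof ordering: [ux..., uy...]."""
    n = lm.n_nodes
    b, A = _ref_gradients(lm)
    tpl = lm.triangles
    Kr, Kc, Kv = [], [], []
    Cr, Cc, Cv = [], [], []
    ML = np.zeros(2 * n)
    for elems, m in _material_per_element(lm, mat):
        D = m.stiffness_voigt()
        Dv = m.viscosity_voigt()
        be, Ae, te = b[elems], A[elems], tpl[elems]
        # B matrix (3 x 6), dof order [ux0,uy0,ux1,uy1,ux2,uy2] locally
        B = np.zeros((len(elems), 3, 6))
        for a in range(3):
            B[:, 0, 2 * a] = be[:, a, 0]
            B[:, 1, 2 * a + 1] = be[:, a, 1]
            B[:, 2, 2 * a] = be[:, a, 1]
            B[:, 2, 2 * a + 1] = be[:, a, 0]
        Ke = np.einsum("m,mia,ij,mjb->mab", Ae, B, D, B)
        Ce = np.einsum("m,mia,ij,mjb->mab", Ae, B, Dv, B)
        ldof = np.empty((len(elems), 6), dtype=np.int64)
        ldof[:, 0::2] = te
        ldof[:, 1::2] = te + n
        Kr.append(np.repeat(ldof, 6, axis=1).ravel())
        Kc.append(np.tile(ldof, (1, 6)).ravel())
        Kv.append(Ke.ravel())
        Cr.append(Kr[-1])
        Cc.append(Kc[-1])
        Cv.append(Ce.ravel())
        mnode = np.repeat(m.rho * Ae / 3.0, 3)
        np.add.at(ML, te.ravel(), mnode)
        np.add.at(ML, te.ravel() + n, mnode)
    K = sp.csr_matrix((np.concatenate(Kv), (np.concatenate(Kr), np.concatenate(Kc))),
                      shape=(2 * n, 2 * n))
    C = sp.csr_matrix((np.concatenate(Cv), (np.concatenate(Cr), np.concatenate(Cc))),
                      shape=(2 * n, 2 * n))
    return K, ML, C


def _traction_forces(lm: LagrangianMesh, bcs: SolidBoundaryData) -> np.ndarray:
    f = np.zeros((lm.n_nodes, 2))
    for (a, bnode), h in zip(bcs.h_segments, bcs.h_values):
        L = np.linalg.norm(lm.ref_coords[bnode] - lm.ref_coords[a])
        f[a] += 0.5 * L * h
        f[bnode] += 0.5 * L * h
    return f


def solve_solid_static(lm: LagrangianMesh, mat, bcs: SolidBoundaryData,
                       fixed_dofs=None) -> np.ndarray:
    """Static equilibrium K u = f with prescribed displacements.

    ``bcs.q`` holds absolute displacements on ``bcs.q_nodes`` (both
    components); ``fixed_dofs`` may pin single dofs (global dof indices in
    [ux..., uy...] ordering) to zero for gauge-type constraints.
    """
    n = lm.n_nodes
    K, _, _ = solid_operators(lm, mat)
    ft = _traction_forces(lm, bcs)
    f = np.concatenate([ft[:, 0], ft[:, 1]])
    fix = np.zeros(2 * n, dtype=bool)
    vals = np.zeros(2 * n)
    if len(bcs.q_nodes):
        fix[bcs.q_nodes] = True
        fix[bcs.q_nodes + n] = True
        vals[bcs.q_nodes] = bcs.q[:, 0]
        vals[bcs.q_nodes + n] = bcs.q[:, 1]
    for d in (fixed_dofs or []):
        fix[d] = True
    free = sp.diags((~fix).astype(float))
    A = (free @ K + sp.diags(fix.astype(float))).tocsc()
    # prescribed displacements move to the RHS of the free rows
    rhs = np.where(fix, vals, f - K @ np.where(fix, vals, 0.0))
    u = spla.spsolve(A, rhs)
    return np.column_stack([u[:n], u[n:]])


class NewmarkSolidSolver:
    """Implicit Newmark-β (β = 1/4, γ = 1/2) integrator for
    ρˢ ü = ∇·σˢ with Dirichlet displacement increments and boundary
    tractions.  Operators are assembled once on the reference mesh (small
    strain)."""

    def __init__(self, lm: LagrangianMesh, mat, beta: float = 0.25,
                 gamma: float = 0.5):
        self.lm = lm
        self.mat = mat
        self.beta = beta
        self.gamma = gamma
        self.K, self.ML, self.C = solid_operators(lm, mat)
        self.n = lm.n_nodes
        self._lhs_cache: tuple[float, object] | None = None

    def _flat(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([x[:, 0], x[:, 1]])

    def _unflat(self, x: np.ndarray) -> np.ndarray:
        return np.column_stack([x[:self.n], x[self.n:]])

    def consistent_acceleration(self, state: SolidState,
                                bcs: SolidBoundaryData,
                                external_force: np.ndarray | None = None) -> np.ndarray:
        """Acceleration satisfying the semidiscrete equation of motion at
        the current state, M a = f − C v − K u (zero on Dirichlet dofs).
        Newmark assumes the starting acceleration is consistent; an
        arbitrary one injects a spurious energy offset at the first step."""
        f = _traction_forces(self.lm, bcs)
        if external_force is not None:
            f = f + external_force
        rhs = (self._flat(f) - self.C @ self._flat(state.v)
               - self.K @ self._flat(state.u))
        a = rhs / self.ML
        if len(bcs.q_nodes):
            qn = np.asarray(bcs.q_nodes, dtype=np.int64)
            a[qn] = 0.0
            a[qn + self.n] = 0.0
        return self._unflat(a)

    def step(self, state: SolidState, bcs: SolidBoundaryData, dt: float,
             external_force: np.ndarray | None = None) -> SolidState:
        """One Newmark step.  ``bcs.q`` are displacement *increments* for
        this step on ``bcs.q_nodes``; ``external_force`` optional nodal
        forces (dyn)."""
        n, beta, gamma = self.n, self.beta, self.gamma
        u0, v0, a0 = self._flat(state.u), self._flat(state.v), self._flat(state.a)
        f = _traction_forces(self.lm, bcs)
        if external_force is not None:
            f = f + external_force
        f = np.concatenate([f[:, 0], f[:, 1]])

        u_pred = u0 + dt * v0 + dt * dt * (0.5 - beta) * a0
        v_pred = v0 + dt * (1.0 - gamma) * a0
        lhs = sp.diags(self.ML) + gamma * dt * self.C + beta * dt * dt * self.K
        rhs = f - self.C @ v_pred - self.K @ u_pred

        fix = np.zeros(2 * n, dtype=bool)
        avals = np.zeros(2 * n)
        if len(bcs.q_nodes):
            qn = np.asarray(bcs.q_nodes, dtype=np.int64)
            u_target = u0.copy()
            u_target[qn] += bcs.q[:, 0]
            u_target[qn + n] += bcs.q[:, 1]
            for idx in (qn, qn + n):
                fix[idx] = True
                avals[idx] = (u_target[idx] - u_pred[idx]) / (beta * dt * dt)
        free = sp.diags((~fix).astype(float))
        A = (free @ lhs + sp.diags(fix.astype(float))).tocsc()
        rhs = np.where(fix, avals, rhs - lhs @ np.where(fix, avals, 0.0))
        a1 = spla.spsolve(A, rhs)
        if not np.all(np.isfinite(a1)):
            raise StepRejectionError("solid solve produced non-finite values")
        u1 = u_pred + beta * dt * dt * a1
        v1 = v_pred + gamma * dt * a1
        new = SolidState(self._unflat(u1), self._unflat(v1), self._unflat(a1),
                         state.t + dt)
        areas = triangle_areas(self.lm.ref_coords + new.u, self.lm.triangles)
        if np.any(areas <= 0):
            raise StepRejectionError("solid step inverted an element")
        return new


def solve_solid_dynamics(lm: LagrangianMesh, mat, state: SolidState,
                         bcs: SolidBoundaryData, dt: float,
                         external_force: np.ndarray | None = None) -> SolidState:
    """One-shot Newmark step (builds the operators; loops should hold a
    :class:`NewmarkSolidSolver`)."""
    return NewmarkSolidSolver(lm, mat).step(state, bcs, dt, external_force)


def update_positions(lm: LagrangianMesh, state: SolidState, dt: float) -> None:
    """Explicit position update uˢ ← uˢ + vˢ Δt (the kinematic update of
    the explicit and semi-implicit schemes); refreshes ``cur_coords``."""
    state.u = state.u + state.v * dt
    state.t += dt
    lm.cur_coords = lm.ref_coords + state.u
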