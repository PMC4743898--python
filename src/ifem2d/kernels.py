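"""Coupling kernels between the Eulerian fluid mesh and the Lagrangian
solid mesh.

Velocity interpolation (fluid → solid) and force distribution (solid →
fluid) use the same weight table φ, so distribution is exactly the
transpose of interpolation.  Two kernel kinds are provided:

``fe-shape``
    Sharp interpolation by the linear shape functions of the host fluid
    element — the weights are the barycentric coordinates of the solid
    node.  Exactly reproducing for linear fields and conservative on
    arbitrary unstructured meshes.  Default.
``discretized-delta``
    Smoothed cosine approximation of the Dirac delta with a support of two
    element sizes, evaluated on the fluid nodes inside the support and
    normalised to partition of unity.

A ``rkpm`` kind (reproducing kernel particle method) is recognised by name
but not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .geometry import EulerianMesh, LagrangianMesh, PointLocator

__all__ = ["CouplingKernel", "build_kernel", "interpolate_to_solid",
           "distribute_to_fluid"]


@dataclass
class CouplingKernel:
    """Sparse weight table φ: rows are solid nodes, columns fluid nodes.

    Invariants: per solid node the weights sum to one (partition of
    unity); weights of the ``fe-shape`` kind are non-negative barycentric
    coordinates with at most three per row.
    """

    kind: str
    weights: sp.csr_matrix          # (n_solid, n_fluid)
    host_elements: np.ndarray | None = None

    @property
    def n_solid(self) -> int:
        return self.weights.shape[0]

    @property
    def n_fluid(self) -> int:
        return self.weights.shape[1]


def build_kernel(em: EulerianMesh, lm_or_points, kind: str = "fe-shape",
                 locator: PointLocator | None = None,
                 support: float = 2.0) -> CouplingKernel:
    """Build the weight table for the current solid configuration.

    Parameters
    ----------
    em : fluid mesh
    lm_or_points : LagrangianMesh (current coordinates are used) or an
        (n, 2) array of points
    kind : "fe-shape" or "discretized-delta"
    locator : optional pre-built :class:`PointLocator` for ``em`` (the
        Eulerian mesh is fixed, so callers re-use one across time steps)
    support : support radius of the discretized delta, in element sizes

    Raises
    ------
    ImmersionError
        if a solid point lies outside the fluid mesh.
    """
    if isinstance(lm_or_points, LagrangianMesh):
        pts = lm_or_points.cur_coords
    else:
        pts = np.atleast_2d(np.asarray(lm_or_points, dtype=float))
    ns, nf = len(pts), em.n_nodes

    if kind == "fe-shape":
        loc = locator if locator is not None else PointLocator(em)
        host, bary = loc.locate(pts)
        cols = em.triangles[host].ravel()
        rows = np.repeat(np.arange(ns), 3)
        W = sp.csr_matrix((bary.ravel(), (rows, cols)), shape=(ns, nf))
        return CouplingKernel(kind, W, host)

    if kind == "discretized-delta":
        # immersion check first: the sharp locator raises if a point is out
        loc = locator if locator is not None else PointLocator(em)
        loc.locate(pts)
        h = em.element_size()
        r = support * h
        tree = cKDTree(em.node_coords)
        rows, cols, vals = [], [], []
        neighbours = tree.query_ball_point(pts, r)
        for i, nb in enumerate(neighbours):
            nb = np.asarray(nb, dtype=np.int64)
            d = np.linalg.norm(em.node_coords[nb] - pts[i], axis=1)
            w = 1.0 + np.cos(np.pi * d / r)  # radial cosine bump
            s = w.sum()
            if s <= 0:
                raise RuntimeError("empty delta-kernel support")
            rows.append(np.full(len(nb), i))
            cols.append(nb)
            vals.append(w / s)
        W = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(ns, nf),
        )
        return CouplingKernel(kind, W)

    if kind == "rkpm":
        raise NotImplementedError("reproducing-kernel (RKPM) weights are not implemented")
    raise ValueError(f"unknown kernel kind: {kind!r}")


def interpolate_to_solid(kernel: CouplingKernel, nodal_field_f: np.ndarray) -> np.ndarray:
    """Interpolate a fluid nodal field to the solid nodes: vˢ = Σ φ vᶠ.

    Linear fields are reproduced exactly by the ``fe-shape`` kind; any
    kind reproduces constants (partition of unity).
    """
    f = np.asarray(nodal_field_f, dtype=float)
    if f.shape[0] != kernel.n_fluid:
        raise ValueError("field is not defined on all fluid nodes")
    return kernel.weights @ f


def distribute_to_fluid(kernel: CouplingKernel, nodal_values_s: np.ndarray) -> np.ndarray:
    """Distribute solid nodal values (already integrated nodal forces) to
    the fluid nodes with the transposed weight table: Fᶠ = φᵀ Fˢ.

    Partition of unity makes this exactly conservative: the fluid-side sum
    equals the solid-side sum for any input.
    """
    s = np.asarray(nodal_values_s, dtype=float)
    if s.shape[0] != kernel.n_solid:
        raise ValueError("values are not defined on all solid nodes")
    return kernel.weights.T @ s
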