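"""Shared fixtures: small meshes and helpers used across the suite."""

import numpy as np
import pytest

from ifem2d.geometry import (EulerianMesh, LagrangianMesh,
                             generate_channel_mesh, generate_disc_mesh)


def walk_boundary_loop(em: EulerianMesh) -> np.ndarray:
    """Order the boundary nodes of a mesh into a closed loop by following
    the (domain-left) oriented boundary edges."""
    edges = em.boundary_edges()
    nxt = {int(a): int(b) for a, b in edges}
    loop = [int(edges[0][0])]
    while True:
        n = nxt[loop[-1]]
        if n == loop[0]:
            break
        loop.append(n)
    return np.array(loop)


def lagrangian_from_eulerian(em: EulerianMesh) -> LagrangianMesh:
    """Re-use a generated Eulerian mesh as a solid mesh (tests only)."""
    return LagrangianMesh(em.node_coords.copy(), em.triangles.copy(),
                          walk_boundary_loop(em))


@pytest.fixture(scope="session")
def channel_em() -> EulerianMesh:
    """4 x 1 channel, h = 0.1 — the reference fluid mesh."""
    return generate_channel_mesh(4.0, 1.0, 0.1)


@pytest.fixture(scope="session")
def square_em() -> EulerianMesh:
    """2 x 2 box, h = 0.1 — hosts immersed discs."""
    return generate_channel_mesh(2.0, 2.0, 0.1)


@pytest.fixture(scope="session")
def disc_lm() -> LagrangianMesh:
    """Unit-scale disc (r = 0.4) immersed in the 2 x 2 box."""
    return generate_disc_mesh((1.0, 1.0), 0.4, 0.05)


@pytest.fixture(scope="session")
def bar_lm() -> LagrangianMesh:
    """1 x 0.1 bar discretised as a solid mesh (cantilever tests)."""
    return lagrangian_from_eulerian(generate_channel_mesh(1.0, 0.1, 0.025))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
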