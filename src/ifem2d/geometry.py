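"""Eulerian and Lagrangian triangle meshes, parametric demo geometries,
point location and mesh I/O.

The fluid lives on a fixed Eulerian triangulation (:class:`EulerianMesh`);
the immersed solid on a moving Lagrangian triangulation
(:class:`LagrangianMesh`) that carries both reference and current
coordinates.  All demo geometries are generated programmatically from a
handful of parameters; no external mesh generator is required.

Coordinates are 2D Cartesian.  The solver works in CGS units (cm, g, s);
generators are unit-agnostic and the case layer converts µm/kPa inputs at
the configuration boundary.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "ConfigurationError",
    "ImmersionError",
    "EulerianMesh",
    "LagrangianMesh",
    "BifurcationGeometry",
    "FoldGeometry",
    "PointLocator",
    "generate_channel_mesh",
    "generate_bifurcation_mesh",
    "generate_disc_mesh",
    "generate_two_layer_fold_mesh",
    "read_mesh",
    "write_mesh",
    "write_vtu",
    "write_state",
    "triangle_areas",
    "polygon_area",
]


class ConfigurationError(ValueError):
    """Invalid or infeasible geometry/configuration parameters."""


class ImmersionError(RuntimeError):
    """A Lagrangian point left the Eulerian domain (the solid must stay
    immersed in the fluid for the interface interpolations to be valid)."""


# ---------------------------------------------------------------------------
# basic mesh containers
# ---------------------------------------------------------------------------

def triangle_areas(coords: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Signed areas of triangles (positive for counter-clockwise nodes)."""
    p0 = coords[tris[:, 0]]
    p1 = coords[tris[:, 1]]
    p2 = coords[tris[:, 2]]
    d1, d2 = p1 - p0, p2 - p0
    return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])


def polygon_area(loop_coords: np.ndarray) -> float:
    """Shoelace area of a closed polygon given by its ordered vertices."""
    x = loop_coords[:, 0]
    y = loop_coords[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _ensure_ccw(coords: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Return a copy of ``tris`` with every triangle counter-clockwise."""
    tris = np.array(tris, dtype=np.int64)
    a = triangle_areas(coords, tris)
    flip = a < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def _boundary_edges(tris: np.ndarray) -> np.ndarray:
    """Edges that belong to exactly one triangle, oriented as in the
    (CCW) triangle so that the domain lies to their left."""
    edges = np.concatenate(
        [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]], axis=0
    )
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    return edges[counts[inv] == 1]


@dataclass
class EulerianMesh:
    """Fixed background fluid mesh.

    Parameters
    ----------
    node_coords : (N, 2) float array
    triangles : (M, 3) int array, counter-clockwise node triples
    boundary_tags : dict mapping tag name ("inlet", "outlet", "wall", ...)
        to an array of node indices.  A boundary edge carries a tag when
        both of its endpoints do; untagged boundary edges are allowed.
    """

    node_coords: np.ndarray
    triangles: np.ndarray
    boundary_tags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_coords = np.ascontiguousarray(self.node_coords, dtype=float)
        self.triangles = _ensure_ccw(self.node_coords, np.asarray(self.triangles))
        areas = triangle_areas(self.node_coords, self.triangles)
        if np.any(areas <= 0):
            raise ConfigurationError("degenerate (zero-area) triangle in mesh")
        self.boundary_tags = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.boundary_tags.items()
        }
        tree = cKDTree(self.node_coords)
        pairs = tree.query_pairs(1e-12 * (1.0 + float(np.ptp(self.node_coords))))
        if pairs:
            raise ConfigurationError(f"duplicate nodes within tolerance: {sorted(pairs)[:5]}")

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def areas(self) -> np.ndarray:
        return triangle_areas(self.node_coords, self.triangles)

    def boundary_edges(self) -> np.ndarray:
        return _boundary_edges(self.triangles)

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_edges())

    def edge_tag(self, edge: np.ndarray) -> str:
        """Tag of a boundary edge: the first tag containing both endpoints
        (tag insertion order gives precedence), else ``"untagged"``."""
        a, b = int(edge[0]), int(edge[1])
        for name, nodes in self.boundary_tags.items():
            s = set(nodes.tolist())
            if a in s and b in s:
                return name
        return "untagged"

    def element_size(self) -> float:
        """Representative element size: median of sqrt(2*area)."""
        return float(np.median(np.sqrt(2.0 * self.areas)))

    def lumped_areas(self) -> np.ndarray:
        """Nodal control areas (row sums of the lumped P1 mass matrix)."""
        w = np.zeros(self.n_nodes)
        a3 = np.repeat(self.areas / 3.0, 3)
        np.add.at(w, self.triangles.ravel(), a3)
        return w


@dataclass
class LagrangianMesh:
    """Moving solid mesh with reference (``ref_coords``) and current
    (``cur_coords``) configurations.

    ``boundary_loop`` is the ordered (counter-clockwise) node index cycle of
    the solid boundary Γˢ, which coincides with the fluid–structure
    interface.  ``element_sets`` optionally partitions elements into named
    material regions (e.g. the cover/body layers of a two-layer fold).
    """

    ref_coords: np.ndarray
    triangles: np.ndarray
    boundary_loop: np.ndarray
    cur_coords: np.ndarray | None = None
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ref_coords = np.ascontiguousarray(self.ref_coords, dtype=float)
        self.triangles = _ensure_ccw(self.ref_coords, np.asarray(self.triangles))
        self.boundary_loop = np.asarray(self.boundary_loop, dtype=np.int64)
        if self.cur_coords is None:
            self.cur_coords = self.ref_coords.copy()
        else:
            self.cur_coords = np.ascontiguousarray(self.cur_coords, dtype=float)
        # boundary loop must be a closed simple polygon with positive area
        if len(np.unique(self.boundary_loop)) != len(self.boundary_loop):
            raise ConfigurationError("boundary loop revisits a node")
        if polygon_area(self.ref_coords[self.boundary_loop]) <= 0:
            self.boundary_loop = self.boundary_loop[::-1].copy()

    @property
    def n_nodes(self) -> int:
        return self.ref_coords.shape[0]

    @property
    def areas(self) -> np.ndarray:
        return triangle_areas(self.cur_coords, self.triangles)

    def lumped_areas(self, reference: bool = False) -> np.ndarray:
        coords = self.ref_coords if reference else self.cur_coords
        w = np.zeros(self.n_nodes)
        a = triangle_areas(coords, self.triangles)
        np.add.at(w, self.triangles.ravel(), np.repeat(a / 3.0, 3))
        return w

    def boundary_segments(self) -> np.ndarray:
        """(K, 2) node-index pairs of consecutive boundary-loop nodes."""
        loop = self.boundary_loop
        return np.stack([loop, np.roll(loop, -1)], axis=1)

    def boundary_normals(self) -> tuple[np.ndarray, np.ndarray]:
        """Outward unit normals and lengths of the boundary segments
        (current configuration).  For a CCW loop the outward normal of the
        segment p→q is (dy, -dx)/|pq|."""
        seg = self.boundary_segments()
        d = self.cur_coords[seg[:, 1]] - self.cur_coords[seg[:, 0]]
        lengths = np.hypot(d[:, 0], d[:, 1])
        n = np.stack([d[:, 1], -d[:, 0]], axis=1) / lengths[:, None]
        return n, lengths

    def node_normals(self) -> np.ndarray:
        """Outward unit normal per boundary-loop node (angle-bisector)."""
        n, _ = self.boundary_normals()
        acc = n + np.roll(n, 1, axis=0)
        return acc / np.linalg.norm(acc, axis=1)[:, None]


# ---------------------------------------------------------------------------
# point location
# ---------------------------------------------------------------------------

def _barycentric(coords, tris, pts, elems):
    """Barycentric coordinates of pts[i] in triangle elems[i]."""
    t = tris[elems]
    p0 = coords[t[:, 0]]
    d1 = coords[t[:, 1]] - p0
    d2 = coords[t[:, 2]] - p0
    r = pts - p0
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    l1 = (r[:, 0] * d2[:, 1] - r[:, 1] * d2[:, 0]) / det
    l2 = (d1[:, 0] * r[:, 1] - d1[:, 1] * r[:, 0]) / det
    return np.stack([1.0 - l1 - l2, l1, l2], axis=1)


class PointLocator:
    """Locate points in a fixed triangulation.

    Candidate elements are found through a KD-tree of element centroids
    (built once; the Eulerian mesh never moves), then the barycentric test
    picks the host.  Queries are vectorised over the point set.
    """

    #: barycentric slack below which a point counts as outside its best tri
    TOL = 1e-9

    def __init__(self, em: EulerianMesh):
        self.em = em
        self.centroids = em.node_coords[em.triangles].mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self._k0 = min(16, len(em.triangles))

    def locate(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Host element and barycentric coordinates for each point.

        Raises
        ------
        ImmersionError
            if any point lies outside the mesh (beyond barycentric slack).
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        n = len(pts)
        host = np.full(n, -1, dtype=np.int64)
        bary = np.zeros((n, 3))
        pending = np.arange(n)
        k = self._k0
        while len(pending) and k <= len(self.em.triangles):
            _, cand = self.tree.query(pts[pending], k=k)
            cand = np.atleast_2d(cand)
            best_b = np.full((len(pending), 3), -np.inf)
            best_e = np.full(len(pending), -1, dtype=np.int64)
            best_min = np.full(len(pending), -np.inf)
            for j in range(cand.shape[1]):
                b = _barycentric(
                    self.em.node_coords, self.em.triangles, pts[pending], cand[:, j]
                )
                m = b.min(axis=1)
                upd = m > best_min
                best_min[upd] = m[upd]
                best_b[upd] = b[upd]
                best_e[upd] = cand[upd, j]
            ok = best_min >= -self.TOL
            idx = pending[ok]
            host[idx] = best_e[ok]
            bary[idx] = np.clip(best_b[ok], 0.0, None)
            bary[idx] /= bary[idx].sum(axis=1)[:, None]
            pending = pending[~ok]
            if k == len(self.em.triangles):
                break
            k = min(4 * k, len(self.em.triangles))
        if len(pending):
            raise ImmersionError(
                f"{len(pending)} point(s) outside the fluid domain, e.g. "
                f"{pts[pending[0]]}; the solid must remain immersed"
            )
        return host, bary


def locate_points(em: EulerianMesh, pts: np.ndarray):
    """One-shot convenience wrapper around :class:`PointLocator`."""
    return PointLocator(em).locate(pts)


# ---------------------------------------------------------------------------
# parametric generators
# ---------------------------------------------------------------------------

def generate_channel_mesh(length: float, height: float, h: float) -> EulerianMesh:
    """Structured rectangular channel [0, L] × [0, H] with tagged
    inlet (x=0), outlet (x=L) and wall (y=0, y=H) node sets.

    Each grid quad is split into two triangles with alternating diagonals
    so the mesh has no global directional bias.
    """
    if length <= 0 or height <= 0 or h <= 0:
        raise ConfigurationError("channel dimensions and element size must be positive")
    nx = max(1, round(length / h))
    ny = max(1, round(height / h))
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    coords = np.stack([X.ravel(), Y.ravel()], axis=1)

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]
    tol = 1e-12 * max(length, height)
    tags = {
        "inlet": np.where(np.abs(coords[:, 0]) < tol)[0],
        "outlet": np.where(np.abs(coords[:, 0] - length) < tol)[0],
        "wall": np.where(
            (np.abs(coords[:, 1]) < tol) | (np.abs(coords[:, 1] - height) < tol)
        )[0],
    }
    return EulerianMesh(coords, np.array(tris), tags)


def channel_node_count(length: float, height: float, h: float) -> int:
    """Node count of :func:`generate_channel_mesh` from the template formula."""
    return (max(1, round(length / h)) + 1) * (max(1, round(height / h)) + 1)


def generate_disc_mesh(center, radius: float, h: float) -> LagrangianMesh:
    """Disc meshed by concentric rings of nodes; boundary nodes lie exactly
    on the circle.  The polygonal area converges to πr² as h → 0."""
    if radius <= 0:
        raise ConfigurationError("radius must be positive")
    if h >= radius:
        raise ConfigurationError("element size must be smaller than the radius")
    center = np.asarray(center, dtype=float)
    n_r = max(2, round(radius / h))
    dr = radius / n_r
    pts = [center.copy()]
    ring_start = []
    ring_count = []
    for k in range(1, n_r + 1):
        r = k * dr
        m = max(6, int(round(2.0 * math.pi * r / dr)))
        ang = 2.0 * math.pi * np.arange(m) / m
        ring_start.append(len(pts))
        ring_count.append(m)
        for a in ang:
            pts.append(center + r * np.array([math.cos(a), math.sin(a)]))
    pts = np.array(pts)
    tri = Delaunay(pts)
    keep = triangle_areas(pts, tri.simplices) > 1e-12 * dr * dr
    tris = tri.simplices[keep]
    outer = np.arange(ring_start[-1], ring_start[-1] + ring_count[-1])
    return LagrangianMesh(pts, tris, outer)


@dataclass
class BifurcationGeometry:
    """Parametric Y-bifurcation: a mother channel of diameter ``w0`` splits
    into an upper daughter (diameter ``w1``, branch angle ``beta1`` above
    the axis) and a lower daughter (``w2``, ``beta2`` below).  The junction
    corners are rounded with fillet radius ``fillet`` for a smooth
    branching transition.  Units follow the caller (the demo case uses µm).
    """

    w0: float = 8.0
    diameter_ratio: float = 1.0      # r_d = w1 / w2
    beta1: float = math.pi / 4
    beta2: float = math.pi / 4
    fillet: float = 3.0
    mother_length: float = 20.0
    daughter_length: float = 16.0
    h: float = 1.0                   # target element size

    @property
    def w1(self) -> float:
        # keep the flow area comparable across ratios: w1*w2 ≈ w0²·k is not
        # prescribed; the printed cases fix w0 and the ratio, so we take
        # w2 = w0 / sqrt(r_d) and w1 = r_d * w2 (w1·w2 = w0²).
        return self.diameter_ratio * self.w2

    @property
    def w2(self) -> float:
        return self.w0 / math.sqrt(self.diameter_ratio)

    def validate(self) -> None:
        if min(self.w0, self.w1, self.w2, self.h) <= 0:
            raise ConfigurationError("diameters and element size must be positive")
        if self.mother_length <= 0 or self.daughter_length <= 0:
            raise ConfigurationError("branch lengths must be positive")
        if self.diameter_ratio <= 0:
            raise ConfigurationError("diameter ratio must be positive")
        if not (0 < self.beta1 < math.pi / 2) or not (0 < self.beta2 < math.pi / 2):
            raise ConfigurationError("branch angles must lie in (0, π/2)")
        if self.beta1 + self.beta2 < 0.15:
            raise ConfigurationError("branches overlap (angles too small)")
        if self.fillet < 0 or self.fillet > 2 * self.w0:
            raise ConfigurationError("fillet radius out of range")

    @property
    def symmetric(self) -> bool:
        return (
            abs(self.diameter_ratio - 1.0) < 1e-12
            and abs(self.beta1 - self.beta2) < 1e-12
        )


def _strip(p0, direction, length, width):
    """Shapely rectangle of given axis, length and width, centered laterally."""
    from shapely.geometry import Polygon

    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    t = np.array([-d[1], d[0]])
    p0 = np.asarray(p0, dtype=float)
    c = [
        p0 + 0.5 * width * t,
        p0 - 0.5 * width * t,
        p0 + length * d - 0.5 * width * t,
        p0 + length * d + 0.5 * width * t,
    ]
    return Polygon([c[0], c[1], c[2], c[3]])


def _resample_ring(coords: np.ndarray, h: float) -> np.ndarray:
    """Resample a closed polyline at ~h spacing, keeping original vertices."""
    out = []
    n = len(coords)
    for i in range(n):
        a = coords[i]
        b = coords[(i + 1) % n]
        seg = np.linalg.norm(b - a)
        out.append(a)
        k = int(seg // h)
        for j in range(1, k + 1):
            s = j / (k + 1)
            out.append((1 - s) * a + s * b)
    return np.array(out)


def _hex_lattice(xmin, xmax, ymin, ymax, h):
    """Triangular lattice of points covering a bounding box, with rows
    symmetric about y = (ymin+ymax)/2 so mirror-symmetric domains receive
    mirror-symmetric interior points."""
    dy = h * math.sqrt(3) / 2
    yc = 0.5 * (ymin + ymax)
    n_up = int((ymax - yc) / dy) + 1
    rows = [yc + k * dy for k in range(-n_up, n_up + 1)]
    pts = []
    for irow, y in enumerate(rows):
        if y < ymin - 1e-12 or y > ymax + 1e-12:
            continue
        off = 0.0 if (irow % 2 == 0) else 0.5 * h
        x = xmin + off
        while x <= xmax:
            pts.append((x, y))
            x += h
    return np.array(pts) if pts else np.empty((0, 2))


def generate_bifurcation_mesh(geom: BifurcationGeometry) -> EulerianMesh:
    """Unstructured triangulation of a Y-bifurcation built from the union
    of three channel strips, fillet-rounded junction corners, and a
    Delaunay triangulation of boundary + interior lattice points.

    Tags: ``inlet`` (mother end), ``outlet1`` (upper daughter end),
    ``outlet2`` (lower daughter end), ``wall`` (everything else).
    """
    import shapely
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    geom.validate()
    h = geom.h
    Lm, Ld = geom.mother_length, geom.daughter_length
    d1 = np.array([math.cos(geom.beta1), math.sin(geom.beta1)])
    d2 = np.array([math.cos(geom.beta2), -math.sin(geom.beta2)])
    extra = 2.0 * max(geom.w0, geom.w1, geom.w2)
    back = 0.6 * geom.w0      # small backward overlap into the junction
    mother = _strip([-Lm - extra, 0.0], [1.0, 0.0], Lm + extra, geom.w0)
    b1 = _strip(-back * d1, d1, Ld + back + extra, geom.w1)
    b2 = _strip(-back * d2, d2, Ld + back + extra, geom.w2)
    poly = unary_union([mother, b1, b2])
    rf = geom.fillet
    if rf > 0:
        poly = (
            poly.buffer(rf, quad_segs=24)
            .buffer(-2 * rf, quad_segs=24)
            .buffer(rf, quad_segs=24)
        )
    # clean clipped ends: inlet plane x = -Lm, outlet planes at axial
    # distance Ld along each daughter axis
    big = 10 * (Lm + Ld + extra)
    clip = Polygon([(-Lm, -big), (big, -big), (big, big), (-Lm, big)])
    for d in (d1, d2):
        t = np.array([-d[1], d[0]])
        o = Ld * d
        clip = clip.intersection(
            Polygon([o + big * t, o - big * t, o - big * t - big * d, o + big * t - big * d])
        )
    poly = poly.intersection(clip)
    if poly.geom_type != "Polygon" or poly.area <= 0:
        raise ConfigurationError("infeasible bifurcation geometry (branches overlap)")

    ring = np.array(poly.exterior.coords[:-1])
    bnd = _resample_ring(ring, h)
    xmin, ymin, xmax, ymax = poly.bounds
    inner = _hex_lattice(xmin, xmax, ymin, ymax, h)
    shrunk = poly.buffer(-0.7 * h)
    if len(inner):
        inside = shapely.contains_xy(shrunk, inner[:, 0], inner[:, 1])
        inner = inner[inside]
    pts = np.vstack([bnd, inner]) if len(inner) else bnd

    if geom.symmetric:
        # exact mirror symmetry of the point set about the mother axis
        pts[np.abs(pts[:, 1]) < 1e-9 * geom.w0, 1] = 0.0
        upper = pts[pts[:, 1] >= 0.0]
        lower = upper[upper[:, 1] > 0.0] * np.array([1.0, -1.0])
        pts = np.vstack([upper, lower])

    # deduplicate
    tree = cKDTree(pts)
    groups = tree.query_ball_tree(tree, 0.2 * h)
    keep = np.ones(len(pts), dtype=bool)
    for i, g in enumerate(groups):
        if keep[i]:
            for j in g:
                if j > i:
                    keep[j] = False
    pts = pts[keep]

    tri = Delaunay(pts)
    cent = pts[tri.simplices].mean(axis=1)
    inside = shapely.contains_xy(poly.buffer(1e-9 * geom.w0), cent[:, 0], cent[:, 1])
    good = np.abs(triangle_areas(pts, tri.simplices)) > 1e-6 * h * h
    tris = tri.simplices[inside & good]
    used = np.unique(tris)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    coords = pts[used]
    tris = remap[tris]

    tol = 0.05 * h
    tags: dict[str, np.ndarray] = {}
    tags["inlet"] = np.where(np.abs(coords[:, 0] + Lm) < tol)[0]
    for name, d in (("outlet1", d1), ("outlet2", d2)):
        axial = coords @ d
        tags[name] = np.where(np.abs(axial - Ld) < tol)[0]
    em = EulerianMesh(coords, tris, tags)
    bn = em.boundary_nodes()
    tagged = np.concatenate([tags["inlet"], tags["outlet1"], tags["outlet2"]])
    em.boundary_tags["wall"] = np.setdiff1d(bn, tagged)
    return em


@dataclass
class FoldGeometry:
    """Two-layer elastic fold attached to a channel wall.

    The fold is a smooth hump of length ``length`` and peak protrusion
    ``height`` measured from the wall toward the channel centerline, with a
    blunt profile so the clamped ends have finite thickness.  Elements with
    through-thickness coordinate beyond ``1 - cover_fraction`` belong to
    the soft ``cover`` layer; the rest to the stiffer ``body`` layer.
    """

    base_x: float = 0.3
    length: float = 0.4
    height: float = 0.085
    channel_height: float = 0.2
    cover_fraction: float = 0.3
    end_fraction: float = 0.18      # relative end thickness of the profile
    n_length: int = 16
    n_thickness: int = 5

    def validate(self) -> None:
        if not (0 < self.cover_fraction < 1):
            raise ConfigurationError("cover fraction must be in (0, 1)")
        if self.cover_fraction >= 1.0:
            raise ConfigurationError("layer fractions sum to more than one")
        if self.height <= 0 or self.length <= 0:
            raise ConfigurationError("fold dimensions must be positive")
        if 2 * self.height >= self.channel_height:
            raise ConfigurationError("folds overlap the channel centerline")


def _fold_profile(s: np.ndarray, geom: FoldGeometry) -> np.ndarray:
    e = geom.end_fraction
    return geom.height * (e + (1.0 - e) * np.sin(math.pi * s))


def generate_two_layer_fold_mesh(geom: FoldGeometry) -> tuple[LagrangianMesh, LagrangianMesh]:
    """Mirrored pair of two-layer folds (lower attached to y=0, upper to
    y=channel_height), as structured triangulated patches with per-element
    ``cover``/``body`` labels."""
    geom.validate()
    ns, nt = geom.n_length, geom.n_thickness
    s = np.linspace(0.0, 1.0, ns + 1)
    t = np.linspace(0.0, 1.0, nt + 1)
    prof = _fold_profile(s, geom)
    X = geom.base_x + s[:, None] * geom.length * np.ones_like(t)[None, :]
    Y = t[None, :] * prof[:, None]
    coords = np.stack([X.ravel(), Y.ravel()], axis=1)

    def nid(i, j):
        return i * (nt + 1) + j

    tris, tmid = [], []
    for i in range(ns):
        for j in range(nt):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
                tmid += [(t[j] + t[j] + t[j + 1]) / 3, (t[j] + t[j + 1] + t[j + 1]) / 3]
            else:
                tris += [[a, b, d], [b, c, d]]
                tmid += [(t[j] + t[j] + t[j + 1]) / 3, (t[j] + t[j + 1] + t[j + 1]) / 3]
    tris = np.array(tris)
    tmid = np.array(tmid)
    cover = np.where(tmid > 1.0 - geom.cover_fraction)[0]
    body = np.setdiff1d(np.arange(len(tris)), cover)

    # boundary loop of the structured patch (CCW): bottom, right, top, left
    bottom = [nid(i, 0) for i in range(ns + 1)]
    right = [nid(ns, j) for j in range(1, nt + 1)]
    top = [nid(i, nt) for i in range(ns - 1, -1, -1)]
    left = [nid(0, j) for j in range(nt - 1, 0, -1)]
    loop = np.array(bottom + right + top + left)

    lower = LagrangianMesh(coords, tris, loop,
                           element_sets={"cover": cover, "body": body})
    mirrored = coords * np.array([1.0, -1.0]) + np.array([0.0, geom.channel_height])
    upper = LagrangianMesh(mirrored, tris, loop,
                           element_sets={"cover": cover, "body": body})
    return lower, upper


# ---------------------------------------------------------------------------
# mesh I/O: Gmsh MSH 2.2 ASCII in, VTU ASCII out
# ---------------------------------------------------------------------------

def write_mesh(path: str, em: EulerianMesh) -> None:
    """Write an Eulerian mesh as Gmsh MSH 2.2 ASCII.  Boundary tags are
    stored as physical line elements over tagged boundary edges; node
    coordinates are written with full precision so a round trip is
    bit-exact."""
    tag_names = list(em.boundary_tags)
    tag_ids = {name: i + 1 for i, name in enumerate(tag_names)}
    bedges = em.boundary_edges()
    lines = []
    for e in bedges:
        name = em.edge_tag(e)
        if name != "untagged":
            lines.append((tag_ids[name], int(e[0]), int(e[1])))
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write("$PhysicalNames\n%d\n" % len(tag_names))
        for name in tag_names:
            f.write('1 %d "%s"\n' % (tag_ids[name], name))
        f.write("$EndPhysicalNames\n$Nodes\n%d\n" % em.n_nodes)
        for i, (x, y) in enumerate(em.node_coords):
            f.write("%d %.17g %.17g 0\n" % (i + 1, x, y))
        f.write("$EndNodes\n$Elements\n%d\n" % (len(lines) + len(em.triangles)))
        eid = 1
        for pid, a, b in lines:
            f.write("%d 1 2 %d %d %d %d\n" % (eid, pid, pid, a + 1, b + 1))
            eid += 1
        for t in em.triangles:
            f.write("%d 2 2 0 0 %d %d %d\n" % (eid, t[0] + 1, t[1] + 1, t[2] + 1))
            eid += 1
        f.write("$EndElements\n")


def read_mesh(path: str) -> EulerianMesh:
    """Read a Gmsh MSH 2.2 ASCII file into an :class:`EulerianMesh`.
    Physical line elements become boundary node-set tags."""
    with open(path) as f:
        tokens = f.read().split("\n")
    it = iter(tokens)
    names: dict[int, str] = {}
    coords = None
    tris: list[list[int]] = []
    tag_nodes: dict[str, set[int]] = {}
    for line in it:
        if line.startswith("$PhysicalNames"):
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split(None, 2)
                names[int(parts[1])] = parts[2].strip().strip('"')
            next(it)  # $End
        elif line.startswith("$Nodes"):
            n = int(next(it))
            coords = np.empty((n, 2))
            for k in range(n):
                parts = next(it).split()
                coords[int(parts[0]) - 1] = [float(parts[1]), float(parts[2])]
            next(it)
        elif line.startswith("$Elements"):
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                conn = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype == 2:
                    tris.append(conn)
                elif etype == 1 and ntags >= 1:
                    name = names.get(int(parts[3]))
                    if name:
                        tag_nodes.setdefault(name, set()).update(conn)
            next(it)
    if coords is None or not tris:
        raise ConfigurationError(f"no triangle mesh found in {path}")
    tags = {k: np.array(sorted(v), dtype=np.int64) for k, v in tag_nodes.items()}
    return EulerianMesh(coords, np.array(tris), tags)


def write_vtu(path: str, coords: np.ndarray, tris: np.ndarray,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Minimal ASCII VTU (unstructured grid, triangle cells) writer."""
    coords = np.asarray(coords, dtype=float)
    tris = np.asarray(tris, dtype=np.int64)
    n, m = len(coords), len(tris)

    def data_array(name, arr):
        arr = np.asarray(arr, dtype=float)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        if ncomp == 2:  # VTK wants 3-component vectors
            arr = np.column_stack([arr, np.zeros(len(arr))])
            ncomp = 3
        body = "\n".join(" ".join("%.9g" % v for v in np.atleast_1d(row))
                         for row in arr)
        return (f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n</DataArray>\n')

    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        f.write(f'<UnstructuredGrid><Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n')
        f.write("<Points>\n")
        f.write(data_array("Points", np.column_stack([coords, np.zeros(n)])))
        f.write("</Points>\n<Cells>\n")
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        f.write("\n".join(" ".join(map(str, t)) for t in tris))
        f.write('\n</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
        f.write(" ".join(str(3 * (i + 1)) for i in range(m)))
        f.write('\n</DataArray>\n<DataArray type="UInt8" Name="types" format="ascii">\n')
        f.write(" ".join("5" for _ in range(m)))
        f.write("\n</DataArray>\n</Cells>\n")
        f.write("<PointData>\n")
        for k, v in (point_data or {}).items():
            f.write(data_array(k, v))
        f.write("</PointData>\n<CellData>\n")
        for k, v in (cell_data or {}).items():
            f.write(data_array(k, v))
        f.write("</CellData>\n</Piece></UnstructuredGrid></VTKFile>\n")


def write_state(run_dir: str, step: int, em: EulerianMesh,
                fluid_point_data: dict[str, np.ndarray],
                solids: list[tuple[LagrangianMesh, dict[str, np.ndarray], dict[str, np.ndarray]]]
                ) -> None:
    """Write one output frame: the fluid fields on the Eulerian mesh and,
    per immersed body, the solid fields on its current configuration."""
    os.makedirs(run_dir, exist_ok=True)
    write_vtu(os.path.join(run_dir, f"fluid_{step:05d}.vtu"),
              em.node_coords, em.triangles, point_data=fluid_point_data)
    for i, (lm, pdata, cdata) in enumerate(solids):
        write_vtu(os.path.join(run_dir, f"solid{i}_{step:05d}.vtu"),
                  lm.cur_coords, lm.triangles, point_data=pdata, cell_data=cdata)
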