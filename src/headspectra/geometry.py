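"""Sensor-layout geometry: equidistant spherical point sets, triangulation,
edge statistics, spatial Nyquist limits and open-cap extraction.

EEG sensor layouts are modelled as triangle meshes whose vertices are the
sensor positions.  All coordinates are in millimetres with the origin at the
sphere centre.  The spatial Nyquist limit of a mesh is the worst-case bound
derived from its maximum edge length ``h_max``::

    k_N = pi / h_max,   omega_N = 1 / (2 h_max),   lambda_N = 2 h_max
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull


class TriangulationError(RuntimeError):
    """Raised when a point set cannot be triangulated."""


class EmptySelectionError(ValueError):
    """Raised when a mesh extraction selects no triangles."""


@dataclass(frozen=True)
class TriMesh:
    """Triangle mesh: sensor positions (mm) and vertex-index triples.

    Closed meshes (no boundary edges) have Euler characteristic 2; open caps
    extracted from a sphere have disc topology (Euler characteristic 1).
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be an (m, 3) index array")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise ValueError("triangle indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, sorted vertex pairs, shape (E, 2)."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def _edge_counts(self) -> np.ndarray:
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return counts

    @property
    def boundary_edge_count(self) -> int:
        return int(np.sum(self._edge_counts() == 1))

    @property
    def is_closed(self) -> bool:
        return self.n_triangles > 0 and self.boundary_edge_count == 0

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + self.n_triangles

    @property
    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )

    @property
    def area(self) -> float:
        return float(self.triangle_areas.sum())

    def validate(self) -> None:
        """Check edge manifoldness and positive triangle areas."""
        counts = self._edge_counts()
        if np.any(counts > 2):
            raise ValueError("non-manifold mesh: an edge belongs to >2 triangles")
        bad = np.flatnonzero(self.triangle_areas <= 0.0)
        if bad.size:
            raise ValueError(f"degenerate triangle(s) with zero area: {bad.tolist()}")

    def scaled(self, factor: float) -> "TriMesh":
        return TriMesh(self.vertices * factor, self.triangles)


@dataclass(frozen=True)
class MeshStats:
    """Edge-length statistics of a layout mesh (mm)."""

    h_mean: float
    h_sd: float
    h_max: float
    n_vertices: int
    n_triangles: int


@dataclass(frozen=True)
class NyquistLimits:
    """Spatial Nyquist wavenumber/frequency/wavelength of a mesh."""

    k_N: float  # rad / mm
    omega_N: float  # 1 / mm
    lambda_N: float  # mm


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = golden * i
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _hull_edges(points: np.ndarray) -> np.ndarray:
    hull = ConvexHull(points)
    e = np.concatenate(
        [hull.simplices[:, [0, 1]], hull.simplices[:, [1, 2]], hull.simplices[:, [2, 0]]]
    )
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a seeded generator (QR of Gaussian)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def equidistant_sphere_points(
    n: int,
    radius: float,
    seed: int = 0,
    *,
    step: float = 0.2,
    force_scale: float = 1.2,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> np.ndarray:
    """Generate ``n`` approximately equidistant points on a sphere.

    A Fibonacci lattice is rotated and jittered by the seeded generator and
    then relaxed: repulsive-only springs act along the edges of the convex
    hull triangulation (the distmesh force model), displacements are projected
    back onto the sphere, and the iteration stops once the largest vertex
    movement drops below ``tol * radius``.  Deterministic for fixed
    ``(n, radius, seed)``.

    Parameters
    ----------
    n : number of points, >= 4.
    radius : sphere radius in mm.
    seed : seed for the initial rotation/jitter.
    """
    if n < 4:
        raise ValueError(f"need at least 4 points, got {n}")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    p = _fibonacci_sphere(n) @ _random_rotation(rng).T
    p = p + 1e-3 * rng.standard_normal(p.shape)
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    for _ in range(max_iter):
        edges = _hull_edges(p)
        d = p[edges[:, 0]] - p[edges[:, 1]]
        length = np.linalg.norm(d, axis=1)
        h0 = force_scale * np.sqrt(np.mean(length**2))
        f = np.maximum(h0 - length, 0.0) / length
        fvec = d * f[:, None]
        disp = np.zeros_like(p)
        np.add.at(disp, edges[:, 0], fvec)
        np.add.at(disp, edges[:, 1], -fvec)
        p_new = p + step * disp
        p_new /= np.linalg.norm(p_new, axis=1, keepdims=True)
        move = np.max(np.linalg.norm(p_new - p, axis=1))
        p = p_new
        if move < tol:
            break
    return p * radius


def triangulate_sphere_points(points: np.ndarray) -> TriMesh:
    """Triangulate points on a common sphere by their convex hull.

    Returns a closed mesh with consistently outward-oriented triangles and
    exactly ``2 n - 4`` faces.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise TriangulationError("need at least 4 points")
    r = np.linalg.norm(points, axis=1)
    if np.ptp(r) > 1e-6 * r.mean():
        raise TriangulationError("points do not lie on a common origin-centred sphere")
    try:
        hull = ConvexHull(points)
    except Exception as exc:  # scipy QhullError on degenerate input
        raise TriangulationError(f"convex hull failed: {exc}") from exc
    if hull.vertices.size != len(points):
        raise TriangulationError("some points fell inside the hull (not spherical)")
    tri = hull.simplices.copy()
    # orient outward: normal . centroid > 0
    v = points[tri]
    normals = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    centroids = v.mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, centroids) < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return TriMesh(points, tri)


def edge_stats(mesh: TriMesh) -> MeshStats:
    """Edge-length statistics over the unique edges of a mesh."""
    if mesh.n_triangles == 0:
        raise ValueError("empty mesh")
    e = mesh.edges
    lengths = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    return MeshStats(
        h_mean=float(lengths.mean()),
        h_sd=float(lengths.std(ddof=0)),
        h_max=float(lengths.max()),
        n_vertices=mesh.n_vertices,
        n_triangles=mesh.n_triangles,
    )


def nyquist_limits(h_max: float) -> NyquistLimits:
    """Worst-case spatial Nyquist limits for maximum edge length ``h_max``."""
    if h_max <= 0:
        raise ValueError("h_max must be positive")
    return NyquistLimits(
        k_N=np.pi / h_max, omega_N=1.0 / (2.0 * h_max), lambda_N=2.0 * h_max
    )


def extract_cap(mesh: TriMesh, axis: np.ndarray, max_angle_deg: float) -> TriMesh:
    """Extract the open cap of a closed mesh within an angular distance of an axis.

    A triangle is kept only if all three of its vertices lie within
    ``max_angle_deg`` of ``axis`` (strict subcomplex; no new vertices).
    """
    if not (0.0 < max_angle_deg <= 180.0):
        raise ValueError("max_angle must be in (0, 180]")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    unit = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    ang = np.degrees(np.arccos(np.clip(unit @ axis, -1.0, 1.0)))
    keep_v = ang <= max_angle_deg + 1e-12
    keep_t = keep_v[mesh.triangles].all(axis=1)
    if not keep_t.any():
        raise EmptySelectionError("cap selection retains no triangles")
    new_index = -np.ones(mesh.n_vertices, dtype=np.int64)
    used = np.unique(mesh.triangles[keep_t])
    new_index[used] = np.arange(len(used))
    return TriMesh(mesh.vertices[used], new_index[mesh.triangles[keep_t]])


# ---------------------------------------------------------------------------
# file formats


def save_mesh(mesh: TriMesh, path: str) -> None:
    """Write a mesh as ASCII OFF or PLY (by file extension)."""
    import trimesh as _trimesh

    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    ext = path.rsplit(".", 1)[-1].lower()
    if ext == "ply":
        data = _trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        with open(path, "wb") as fh:
            fh.write(data)
    elif ext == "off":
        data = _trimesh.exchange.off.export_off(tm)
        with open(path, "w") as fh:
            fh.write(data)
    else:
        raise ValueError(f"unsupported mesh format: {ext}")


def load_mesh(path: str) -> TriMesh:
    import trimesh as _trimesh

    tm = _trimesh.load_mesh(path, process=False)
    return TriMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


def save_layout(points: np.ndarray, path: str, comment: str = "") -> None:
    """Write sensor coordinates as 3-column delimited text (x, y, z in mm)."""
    header = "x_mm,y_mm,z_mm"
    if comment:
        header = comment + "\n" + header
    np.savetxt(path, points, delimiter=",", header=header)


def load_layout(path: str) -> np.ndarray:
    pts = np.loadtxt(path, delimiter=",", comments="#")
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3:
        raise ValueError("layout file must have 3 columns (x, y, z in mm)")
    return pts
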