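"""Simplex-mesh geometry: construction, differential geometry, refinement,
and rasterization to voxel masks.

A 2-simplex mesh is the topological dual of a closed triangulation: one mesh
vertex per triangle, and every vertex has exactly three neighbours.  The
three neighbours define the tangent plane and outward normal at the vertex,
and the *simplex angle* — a signed angle measuring how far the vertex lifts
out of its neighbours' circumscribed circle — encodes the local mean
curvature.  This discrete geometry is what the internal (smoothing) forces
of the deformation act on.

Two derived triangulations are used:

* the *dual triangulation* (one point per polygonal face, one triangle per
  simplex vertex) drives refinement, which subdivides it 1:4 and re-dualizes;
* the *fan triangulation* (each polygonal face fanned around its centroid)
  passes through every simplex vertex and is the surface rasterized to voxel
  masks and written to mesh files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .volume import BinaryMask, ScalarVolume

logger = logging.getLogger(__name__)

_DEG_EPS = 1e-12


class GeometryError(ValueError):
    """Raised for degenerate local configurations (collinear neighbours...)."""


class MeshTopologyError(ValueError):
    """Raised when a mesh violates the closed 2-manifold / 3-connectivity contract."""


# ---------------------------------------------------------------------------
# The mesh container
# ---------------------------------------------------------------------------


@dataclass
class SimplexMesh:
    """Deformable simplex mesh in world (mm) coordinates.

    Attributes
    ----------
    vertices
        ``(n, 3)`` vertex positions.
    neighbors
        ``(n, 3)`` indices of the three neighbours of each vertex, ordered so
        that ``cross(p2 - p1, p3 - p1)`` points outward.
    tri_faces
        ``(n, 3)`` dual-triangulation connectivity: row ``f`` lists the three
        polygonal faces (rings) that simplex vertex ``f`` belongs to; read as
        triangles over the ring centroids it is the dual triangulation.
    rings
        Ordered (cyclic, consistently wound) vertex index array per polygonal
        face of the simplex mesh.
    reference_eps
        ``(n, 3)`` barycentric ("metric") parameters of each vertex's
        tangential equilibrium in its neighbour triangle, stored at
        construction; used by the internal tangential force.
    reference_angle
        ``(n,)`` simplex angle at construction.
    prev_positions
        ``(n, 3)`` positions at the previous time step (inertia term).
    """

    vertices: np.ndarray
    neighbors: np.ndarray
    tri_faces: np.ndarray
    rings: list
    reference_eps: np.ndarray | None = None
    reference_angle: np.ndarray | None = None
    prev_positions: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.neighbors = np.asarray(self.neighbors, dtype=np.int64)
        self.tri_faces = np.asarray(self.tri_faces, dtype=np.int64)
        validate_topology(self.neighbors)
        if self.prev_positions is None:
            self.prev_positions = self.vertices.copy()
        if self.reference_eps is None or self.reference_angle is None:
            self.reset_reference_params()

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.rings)

    def copy(self) -> "SimplexMesh":
        return SimplexMesh(
            self.vertices.copy(),
            self.neighbors.copy(),
            self.tri_faces.copy(),
            [np.array(r) for r in self.rings],
            reference_eps=self.reference_eps.copy(),
            reference_angle=self.reference_angle.copy(),
            prev_positions=self.prev_positions.copy(),
        )

    def reset_reference_params(self) -> None:
        """Record the current geometry as the internal-force equilibrium."""
        geo = simplex_geometry(self)
        self.reference_eps = geo["eps"].copy()
        self.reference_angle = geo["phi"].copy()

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    # -- derived triangulations ----------------------------------------

    def _ring_flat(self):
        if "ring_flat" not in self._cache:
            rid = np.concatenate(
                [np.full(len(r), v, dtype=np.int64) for v, r in enumerate(self.rings)]
            )
            vid = np.concatenate(self.rings).astype(np.int64)
            counts = np.array([len(r) for r in self.rings], dtype=np.int64)
            self._cache["ring_flat"] = (rid, vid, counts)
        return self._cache["ring_flat"]

    def face_centroids(self) -> np.ndarray:
        """Centroid of every polygonal face (= dual-triangulation point)."""
        rid, vid, counts = self._ring_flat()
        acc = np.zeros((self.n_faces, 3))
        np.add.at(acc, rid, self.vertices[vid])
        return acc / counts[:, None]

    def _fan_faces(self) -> np.ndarray:
        """Static fan connectivity: point ids are [face centroids | vertices]."""
        if "fan_faces" not in self._cache:
            tris = []
            R = self.n_faces
            for v, ring in enumerate(self.rings):
                k = len(ring)
                for i in range(k):
                    tris.append((v, R + ring[i], R + ring[(i + 1) % k]))
            self._cache["fan_faces"] = np.array(tris, dtype=np.int64)
        return self._cache["fan_faces"]

    def _lifted_centroids(self) -> np.ndarray:
        """Face centroids lifted along the face normal by the local sagitta.

        A planar ring centroid sits inside a curved surface by about
        ``H * rho^2 / 2`` (mean curvature H, ring radius rho); lifting by
        that amount puts the fan point back on the smooth surface the
        vertices sample, removing the systematic inward volume bias of the
        rasterized masks.
        """
        geo = simplex_geometry(self)
        H = np.sin(geo["phi"]) / np.maximum(geo["r"], _DEG_EPS)
        n = geo["n"]
        rid, vid, counts = self._ring_flat()
        cent = np.zeros((self.n_faces, 3))
        np.add.at(cent, rid, self.vertices[vid])
        cent /= counts[:, None]
        nbar = np.zeros((self.n_faces, 3))
        np.add.at(nbar, rid, n[vid])
        nbar /= np.maximum(np.linalg.norm(nbar, axis=1, keepdims=True), _DEG_EPS)
        Hbar = np.zeros(self.n_faces)
        np.add.at(Hbar, rid, H[vid])
        Hbar /= counts
        d = self.vertices[vid] - cent[rid]
        d2 = np.zeros(self.n_faces)
        np.add.at(d2, rid, np.einsum("ij,ij->i", d, d))
        d2 /= counts
        rho = np.sqrt(d2)
        lift = np.clip(Hbar * d2 / 2.0, -rho, rho)
        return cent + lift[:, None] * nbar

    def surface_points_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Fan triangulation through all simplex vertices: (points, faces)."""
        pts = np.concatenate([self._lifted_centroids(), self.vertices], axis=0)
        return pts, self._fan_faces()

    def to_triangulation(self) -> trimesh.Trimesh:
        """The fan triangulation as a trimesh surface."""
        pts, faces = self.surface_points_faces()
        return trimesh.Trimesh(vertices=pts, faces=faces, process=False)

    def enclosed_volume(self) -> float:
        """Signed volume (mm^3) of the fan surface; positive when wound outward."""
        pts, faces = self.surface_points_faces()
        tri = pts[faces]
        return float(
            np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
        )

    def euler_characteristic(self) -> int:
        """chi of the simplex polyhedron: V - E + F (2 for sphere topology)."""
        n_v = self.n_vertices
        n_e = 3 * n_v // 2
        return n_v - n_e + self.n_faces

    def is_closed(self) -> bool:
        """Every dual-triangulation edge shared by exactly two triangles."""
        edges = np.sort(
            np.concatenate(
                [
                    self.tri_faces[:, [0, 1]],
                    self.tri_faces[:, [1, 2]],
                    self.tri_faces[:, [2, 0]],
                ]
            ),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    # -- graph neighbourhoods ------------------------------------------

    def neighborhood_average(self, scale: int):
        """Row-stochastic sparse operator averaging over the graph ball of
        radius `scale` (vertex itself included).  Cached per scale."""
        key = ("nbhd", scale)
        if key in self._cache:
            return self._cache[key]
        import scipy.sparse as sp

        n = self.n_vertices
        rows = np.repeat(np.arange(n), 3)
        adj = sp.csr_matrix(
            (np.ones(3 * n), (rows, self.neighbors.ravel())), shape=(n, n)
        )
        reach = sp.identity(n, format="csr")
        frontier = sp.identity(n, format="csr")
        for _ in range(int(scale)):
            frontier = frontier @ adj
            reach = reach + frontier
        reach = (reach > 0).astype(float)
        norm = np.asarray(reach.sum(axis=1)).ravel()
        avg = sp.diags(1.0 / norm) @ reach.tocsr()
        self._cache[key] = avg
        return avg


def validate_topology(neighbors: np.ndarray) -> None:
    """Check 3-connectivity and symmetry of the neighbour relation."""
    n = len(neighbors)
    if neighbors.shape != (n, 3):
        raise MeshTopologyError(f"neighbour table must be (n, 3), got {neighbors.shape}")
    for i in range(n):
        nb = neighbors[i]
        if len(set(nb.tolist())) != 3 or i in nb:
            raise MeshTopologyError(f"vertex {i} lacks 3 distinct neighbours: {nb}")
    back = [set(neighbors[j].tolist()) for j in range(n)]
    for i in range(n):
        for j in neighbors[i]:
            if i not in back[j]:
                raise MeshTopologyError(f"asymmetric neighbour pair ({i}, {j})")


# ---------------------------------------------------------------------------
# Construction: dual of a closed triangulation
# ---------------------------------------------------------------------------


def _dualize(points: np.ndarray, faces: np.ndarray) -> SimplexMesh:
    """Simplex mesh dual to a closed, consistently wound triangulation.

    One simplex vertex per triangle (at its centroid); neighbours are the
    edge-adjacent triangles, ordered to inherit the triangulation's winding;
    the polygonal faces are the ordered triangle rings around each
    triangulation point.
    """
    points = np.asarray(points, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    nf = len(faces)
    edge_to_face: dict[tuple[int, int], int] = {}
    for f, (a, b, c) in enumerate(faces):
        edge_to_face[(a, b)] = f
        edge_to_face[(b, c)] = f
        edge_to_face[(c, a)] = f
    neighbors = np.empty((nf, 3), dtype=np.int64)
    for f, (a, b, c) in enumerate(faces):
        neighbors[f] = (
            edge_to_face[(b, a)],
            edge_to_face[(c, b)],
            edge_to_face[(a, c)],
        )
    verts = points[faces].mean(axis=1)

    # ordered rings: walk the triangles around each point following winding
    incident: list[list[int]] = [[] for _ in range(len(points))]
    for f, tri in enumerate(faces):
        for v in tri:
            incident[v].append(f)
    rings: list[np.ndarray] = []
    for v, inc in enumerate(incident):
        f = inc[0]
        ring = [f]
        while len(ring) < len(inc):
            a, b, c = faces[f]
            # predecessor of v in this face's winding
            prev = c if a == v else (a if b == v else b)
            f = edge_to_face[(v, prev)]
            ring.append(f)
        rings.append(np.array(ring, dtype=np.int64))

    mesh = SimplexMesh(verts, neighbors, faces.copy(), rings)
    # orient simplex normals with the triangulation's face normals
    fn = np.cross(
        points[faces[:, 1]] - points[faces[:, 0]],
        points[faces[:, 2]] - points[faces[:, 0]],
    )
    _orient_normals(mesh, fn)
    # wind the fan outward (positive enclosed volume)
    if mesh.enclosed_volume() < 0:
        mesh.rings = [r[::-1].copy() for r in mesh.rings]
        mesh._cache.pop("fan_faces", None)
        mesh._cache.pop("ring_flat", None)
    return mesh


def _orient_normals(mesh: SimplexMesh, target_normals: np.ndarray) -> None:
    """Swap neighbour order where the simplex normal opposes the target."""
    normals = simplex_geometry(mesh)["n"]
    flip = np.einsum("ij,ij->i", normals, target_normals) < 0
    if np.any(flip):
        mesh.neighbors[flip] = mesh.neighbors[flip][:, [0, 2, 1]]
        mesh.reset_reference_params()


def build_simplex_sphere(center, radius: float, subdivisions: int = 1) -> SimplexMesh:
    """Spherical simplex mesh: dual of an icosahedron subdivided `subdivisions`
    times, vertices projected onto the sphere of given `center`/`radius`.

    subdivisions=0 gives the dual of the icosahedron itself (20 vertices, one
    per face); each subdivision quadruples the simplex vertex count.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if subdivisions < 0:
        raise ValueError(f"subdivisions must be >= 0, got {subdivisions}")
    center = np.asarray(center, dtype=float).reshape(3)
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    mesh = _dualize(np.asarray(ico.vertices), np.asarray(ico.faces))
    v = mesh.vertices
    mesh.vertices = center + radius * v / np.linalg.norm(v, axis=1, keepdims=True)
    mesh.prev_positions = mesh.vertices.copy()
    mesh.reset_reference_params()
    return mesh


# ---------------------------------------------------------------------------
# Differential geometry
# ---------------------------------------------------------------------------


def simplex_geometry(mesh: SimplexMesh) -> dict:
    """Vectorized per-vertex simplex geometry.

    Returns, for every vertex: the unit normal ``n`` of the neighbour plane,
    circumcenter ``C`` and circumradius ``r`` of the neighbour triangle, the
    signed elevation ``z`` of the vertex above the plane, the foot point
    ``foot`` with barycentric coordinates ``eps``, and the simplex angle
    ``phi``.

    The simplex angle follows the circumscribed-sphere construction: with
    ``R`` the radius of the sphere through the vertex and its three
    neighbours, ``sin(phi) = (r / R) * sign(z)``, and the sign of
    ``cos(phi)`` distinguishes caps smaller/larger than a hemisphere.  The
    discrete mean curvature is ``H = sin(phi) / r``.
    """
    p = mesh.vertices
    p1 = p[mesh.neighbors[:, 0]]
    p2 = p[mesh.neighbors[:, 1]]
    p3 = p[mesh.neighbors[:, 2]]
    a = p2 - p1
    b = p3 - p1
    cr = np.cross(a, b)
    cr_norm = np.linalg.norm(cr, axis=1)
    scale = np.maximum(np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1), _DEG_EPS)
    degenerate = cr_norm < 1e-9 * scale
    safe = np.where(degenerate, 1.0, cr_norm)
    n = cr / safe[:, None]

    a2 = np.einsum("ij,ij->i", a, a)
    b2 = np.einsum("ij,ij->i", b, b)
    denom = 2.0 * safe**2
    C = p1 + np.cross(a2[:, None] * b - b2[:, None] * a, cr) / denom[:, None]
    r = np.linalg.norm(C - p1, axis=1)

    d = p - p1
    z = np.einsum("ij,ij->i", d, n)
    foot = p - z[:, None] * n

    fa = np.einsum("ij,ij->i", foot - p1, a)
    fb = np.einsum("ij,ij->i", foot - p1, b)
    ab = np.einsum("ij,ij->i", a, b)
    det = np.maximum(a2 * b2 - ab**2, _DEG_EPS)
    u = (b2 * fa - ab * fb) / det
    v = (a2 * fb - ab * fa) / det
    eps = np.stack([1.0 - u - v, u, v], axis=1)

    rho2 = np.einsum("ij,ij->i", foot - C, foot - C)
    small_z = np.abs(z) < 1e-12 * np.maximum(r, 1.0)
    z_safe = np.where(small_z, 1.0, z)
    c_ax = (z**2 + rho2 - r**2) / (2.0 * z_safe)  # sphere-center height above plane
    R = np.sqrt(r**2 + c_ax**2)
    sin_phi = np.clip(r / np.maximum(R, _DEG_EPS), 0.0, 1.0) * np.sign(z)
    cos_phi = np.sqrt(np.clip(1.0 - sin_phi**2, 0.0, 1.0))
    cos_phi = np.where(c_ax * z > 0, -cos_phi, cos_phi)
    phi = np.arctan2(sin_phi, cos_phi)
    phi = np.where(small_z, 0.0, phi)

    return {
        "n": n,
        "C": C,
        "r": r,
        "z": z,
        "foot": foot,
        "eps": eps,
        "phi": phi,
        "degenerate": degenerate,
    }


def vertex_normals(mesh: SimplexMesh) -> np.ndarray:
    """(n, 3) outward unit normals (normal of each vertex's neighbour plane)."""
    return simplex_geometry(mesh)["n"]


def _checked_geometry(mesh: SimplexMesh, i: int) -> dict:
    if not 0 <= i < mesh.n_vertices:
        raise IndexError(f"vertex index {i} out of range [0, {mesh.n_vertices})")
    geo = simplex_geometry(mesh)
    if geo["degenerate"][i]:
        raise GeometryError(f"vertex {i}: collinear neighbour triple")
    return geo


def simplex_angle(mesh: SimplexMesh, i: int) -> float:
    """Signed simplex angle (radians) of vertex `i`; 0 for a flat vertex."""
    return float(_checked_geometry(mesh, i)["phi"][i])


def vertex_normal(mesh: SimplexMesh, i: int) -> np.ndarray:
    """Outward unit normal at vertex `i`."""
    return _checked_geometry(mesh, i)["n"][i]


def mean_curvature(mesh: SimplexMesh, i: int) -> float:
    """Discrete mean curvature H = sin(phi)/r at vertex `i` (1/mm)."""
    geo = _checked_geometry(mesh, i)
    r = geo["r"][i]
    if r < _DEG_EPS:
        raise GeometryError(f"vertex {i}: zero circumradius")
    return float(np.sin(geo["phi"][i]) / r)


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------


def refine(mesh: SimplexMesh, warn_self_intersection: bool = True) -> SimplexMesh:
    """Refined simplex mesh interpolating the input surface (4x vertex count).

    The dual triangulation is subdivided 1:4 at edge midpoints and
    re-dualized.  Each parent vertex's four children are then shifted so the
    central child lands exactly on the parent vertex, which keeps the refined
    surface interpolating the coarse one instead of shrinking toward the
    dual-point centroids.  There is no repair step for self-intersecting
    input — a warning diagnostic is emitted and refinement proceeds.
    """
    if not mesh.is_closed():
        raise MeshTopologyError("refine requires a closed mesh")
    if warn_self_intersection and self_intersects(mesh):
        logger.warning(
            "refining a self-intersecting mesh (%d vertices); masks rasterized "
            "from it may contain holes",
            mesh.n_vertices,
        )
    P = mesh.face_centroids()
    F = mesh.tri_faces
    # 1:4 subdivision with shared edge midpoints
    mid: dict[tuple[int, int], int] = {}
    new_pts = [P]
    next_id = len(P)

    def midpoint(i: int, j: int) -> int:
        nonlocal next_id
        key = (i, j) if i < j else (j, i)
        if key not in mid:
            mid[key] = next_id
            next_id += 1
            new_pts.append(((P[i] + P[j]) / 2.0)[None, :])
        return mid[key]

    nf = len(F)
    new_faces = np.empty((4 * nf, 3), dtype=np.int64)
    for f, (a, b, c) in enumerate(F):
        mab = midpoint(a, b)
        mbc = midpoint(b, c)
        mca = midpoint(c, a)
        new_faces[4 * f + 0] = (a, mab, mca)
        new_faces[4 * f + 1] = (mab, b, mbc)
        new_faces[4 * f + 2] = (mca, mbc, c)
        new_faces[4 * f + 3] = (mab, mbc, mca)  # central child
    points = np.concatenate(new_pts, axis=0)

    out = _dualize(points, new_faces)
    # interpolation correction: central child centroid equals the parent
    # triangle centroid, so shift each family onto the parent vertex
    parent_centroid = P[F].mean(axis=1)
    offset = mesh.vertices - parent_centroid  # (nf, 3)
    out.vertices = out.vertices + np.repeat(offset, 4, axis=0)
    out.prev_positions = out.vertices.copy()
    out.reset_reference_params()
    return out


def self_intersects(mesh: SimplexMesh, max_pairs: int = 2_000_000) -> bool:
    """Broad-phase + exact triangle-pair test for surface self-intersection.

    Uses the fan triangulation; non-adjacent triangle pairs only.  Intended
    as a diagnostic (the deformation pipeline has no repair step).
    """
    pts, faces = mesh.surface_points_faces()
    tris = pts[faces]
    lo = tris.min(axis=1)
    hi = tris.max(axis=1)
    nf = len(tris)
    if nf * nf > max_pairs:
        cell = float(np.median(hi - lo)) * 2.0 + 1e-9
        buckets: dict[tuple, list[int]] = {}
        for f in range(nf):
            c0 = np.floor(lo[f] / cell).astype(int)
            c1 = np.floor(hi[f] / cell).astype(int)
            for ix in range(c0[0], c1[0] + 1):
                for iy in range(c0[1], c1[1] + 1):
                    for iz in range(c0[2], c1[2] + 1):
                        buckets.setdefault((ix, iy, iz), []).append(f)
        cand = set()
        for members in buckets.values():
            for ii in range(len(members)):
                for jj in range(ii + 1, len(members)):
                    cand.add((members[ii], members[jj]))
        pairs = np.array(sorted(cand), dtype=int) if cand else np.empty((0, 2), int)
    else:
        ii, jj = np.triu_indices(nf, k=1)
        pairs = np.stack([ii, jj], axis=1)
    if len(pairs) == 0:
        return False
    keep = np.all(lo[pairs[:, 0]] <= hi[pairs[:, 1]], axis=1) & np.all(
        lo[pairs[:, 1]] <= hi[pairs[:, 0]], axis=1
    )
    pairs = pairs[keep]
    if len(pairs) == 0:
        return False
    shared = np.array(
        [len(set(faces[a]) & set(faces[b])) > 0 for a, b in pairs], dtype=bool
    )
    pairs = pairs[~shared]
    return any(_tri_tri_intersect(tris[a], tris[b]) for a, b in pairs)


def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray) -> bool:
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    d2 = (t2 - t1[0]) @ n1
    if np.all(d2 > 1e-12) or np.all(d2 < -1e-12):
        return False
    n2 = np.cross(t2[1] - t2[0], t2[2] - t2[0])
    d1 = (t1 - t2[0]) @ n2
    if np.all(d1 > 1e-12) or np.all(d1 < -1e-12):
        return False
    for tri, other in ((t1, t2), (t2, t1)):
        for e in range(3):
            if _segment_hits_triangle(other[e], other[(e + 1) % 3], tri):
                return True
    return False


def _segment_hits_triangle(a, b, tri) -> bool:
    eps = 1e-12
    d = b - a
    e1 = tri[1] - tri[0]
    e2 = tri[2] - tri[0]
    h = np.cross(d, e2)
    det = e1 @ h
    if abs(det) < eps:
        return False
    f = 1.0 / det
    s = a - tri[0]
    u = f * (s @ h)
    if u < 0.0 or u > 1.0:
        return False
    q = np.cross(s, e1)
    v = f * (d @ q)
    if v < 0.0 or u + v > 1.0:
        return False
    t = f * (e2 @ q)
    return eps < t < 1.0 - eps


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

# irrational-ish jitter (voxels) so column rays never hit triangle edges or
# vertices exactly; deterministic, identical every run
_JITTER = (np.sqrt(2.0) - 1.0) * 1e-6


def rasterize(mesh: SimplexMesh, grid: ScalarVolume) -> BinaryMask:
    """Voxelize the closed mesh: voxels whose centers lie inside become 1.

    Inside-ness is decided by parity of crossings of a +z ray (in voxel
    space) against the fan triangulation of the mesh.  A self-intersecting
    surface still rasterizes under the parity rule but the result may
    contain holes.
    """
    if not mesh.is_closed():
        raise MeshTopologyError("rasterize requires a closed mesh")
    pts, faces = mesh.surface_points_faces()
    tri = grid.world_to_voxel(pts)[faces]
    nx, ny, nz = grid.shape
    counts = np.zeros((nx, ny, nz + 1), dtype=np.int32)

    A, B, C = tri[:, 0].copy(), tri[:, 1].copy(), tri[:, 2].copy()
    # jitter the surface, not the rays, so integer column coords stay exact
    for t in (A, B, C):
        t[:, 0] -= _JITTER
        t[:, 1] -= _JITTER * 0.7

    det = (B[:, 0] - A[:, 0]) * (C[:, 1] - A[:, 1]) - (B[:, 1] - A[:, 1]) * (
        C[:, 0] - A[:, 0]
    )
    minx = np.maximum(np.ceil(np.minimum.reduce([A[:, 0], B[:, 0], C[:, 0]])), 0).astype(int)
    maxx = np.minimum(np.floor(np.maximum.reduce([A[:, 0], B[:, 0], C[:, 0]])), nx - 1).astype(int)
    miny = np.maximum(np.ceil(np.minimum.reduce([A[:, 1], B[:, 1], C[:, 1]])), 0).astype(int)
    maxy = np.minimum(np.floor(np.maximum.reduce([A[:, 1], B[:, 1], C[:, 1]])), ny - 1).astype(int)

    for f in range(len(tri)):
        if abs(det[f]) < 1e-15 or minx[f] > maxx[f] or miny[f] > maxy[f]:
            continue
        xs = np.arange(minx[f], maxx[f] + 1)
        ys = np.arange(miny[f], maxy[f] + 1)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        ax, ay = A[f, 0], A[f, 1]
        inv = 1.0 / det[f]
        u = ((gx - ax) * (C[f, 1] - ay) - (gy - ay) * (C[f, 0] - ax)) * inv
        v = ((B[f, 0] - ax) * (gy - ay) - (B[f, 1] - ay) * (gx - ax)) * inv
        hit = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        if not np.any(hit):
            continue
        zint = A[f, 2] + u[hit] * (B[f, 2] - A[f, 2]) + v[hit] * (C[f, 2] - A[f, 2])
        k = np.floor(zint).astype(int) + 1  # first voxel center strictly above
        k = np.clip(k, 0, nz)  # below-grid crossings flip the whole column
        np.add.at(counts, (gx[hit], gy[hit], k), 1)

    inside = np.cumsum(counts[:, :, :nz], axis=2) % 2
    return BinaryMask.from_volume_grid(grid, inside.astype(np.uint8))
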