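"""Force terms of the deformation and the per-iteration motion update.

Every vertex of a simplex mesh is a point mass evolved by a damped
Newtonian update::

    p_{t+1} = p_t + (1 - gamma) (p_t - p_{t-1}) + w_int F_int + F_ext

with the external force a weighted sum of image terms, each directed along
the vertex normal (tangential external displacements are what produce
self-intersection, so they are excluded by construction)::

    F_ext = w_grad F_gradient + w_edge F_edge + w_balloon F_balloon
            + w_coll F_collision

* the *internal* force restores the vertex toward its reference tangential
  (metric) position and drives the simplex angle toward the mean angle over
  a graph neighbourhood whose size is the smoothness scale;
* the *gradient* force pulls toward the strongest gradient-magnitude voxel
  in a ball around the vertex;
* the *edge* force pulls toward the brightest voxel along the normal line;
* the *balloon* force inflates along the normal while the vertex sits in
  object-classified territory (indicator between the classified-image
  thresholds T_low and T_high);
* the *collision* force acts only where the vertex has entered another
  mesh's territory (collision energy image = 1) and pulls it to the nearby
  true boundary by a gradient search in a small neighbourhood.

All vectorized entry points (plural names) return ``(n, 3)`` displacement
contributions in mm; the per-vertex singular forms mirror them for one
index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mesh import SimplexMesh, simplex_geometry
from .volume import BinaryMask, ScalarVolume

logger = logging.getLogger(__name__)


class ForceError(RuntimeError):
    """Raised when a non-finite force reaches the motion update."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class StageParameters:
    """Weights and scales for one deformation stage.

    All force weights range from 0 (no strength) to 1 (highest strength).
    ``smoothness_scale`` is the graph-neighbourhood size used by the
    internal normal force; ``gamma`` the damping of the inertia term;
    search radii are in voxels; ``t_low``/``t_high`` bound the classified
    intensities the balloon force inflates through.
    """

    w_internal: float = 0.9
    w_gradient: float = 0.3
    w_edge: float = 0.0
    w_balloon: float = 0.08
    w_collision: float = 0.4
    smoothness_scale: int = 12
    gamma: float = 0.65
    gradient_search_radius: int = 3
    collision_search_radius: int = 5
    t_low: float = -0.99
    t_high: float = 1.0
    gradient_floor: float = 0.0
    max_iterations: int = 200
    max_displacement: float = 0.5  # voxels; per-iteration displacement cap

    def __post_init__(self) -> None:
        for name in ("w_internal", "w_gradient", "w_edge", "w_balloon", "w_collision"):
            w = getattr(self, name)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {w}")
        if self.smoothness_scale < 1:
            raise ValueError(f"smoothness_scale must be >= 1, got {self.smoothness_scale}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.t_low >= self.t_high:
            raise ValueError(f"need t_low < t_high, got {self.t_low} >= {self.t_high}")


# ---------------------------------------------------------------------------
# Internal force
# ---------------------------------------------------------------------------


def _elevation(r: np.ndarray, d: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Delingette elevation L(r, d, phi): height above the neighbour plane of
    a point whose foot sits at distance d from the circumcenter, on the
    sphere that realizes simplex angle phi over a circle of radius r."""
    rr = np.maximum(r**2 - d**2, 0.0)
    t = np.tan(phi)
    near_perp = np.abs(np.abs(phi) - np.pi / 2) < 1e-8
    t_safe = np.where(near_perp, 1.0, t)
    sgn = np.where(np.abs(phi) <= np.pi / 2, 1.0, -1.0)
    root = np.sqrt(np.maximum(r**2 + rr * t_safe**2, 0.0))
    denom = sgn * root + r
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    L = rr * t_safe / denom
    L = np.where(near_perp, np.sign(phi) * np.sqrt(rr), L)
    return L


def internal_forces(mesh: SimplexMesh, params: StageParameters) -> np.ndarray:
    """Tangential + normal internal force for every vertex.

    The tangential part moves each vertex toward the position its stored
    reference barycentric (metric) parameters assign in the current
    neighbour triangle; the normal part drives the simplex angle toward the
    mean of the current angles over the smoothness neighbourhood
    (C1-style continuity), which smooths curvature without imposing shape
    memory.
    """
    geo = simplex_geometry(mesh)
    if np.any(geo["degenerate"]):
        logger.warning(
            "internal force: %d degenerate vertex neighbourhoods, zero force there",
            int(geo["degenerate"].sum()),
        )
    nbrs = mesh.neighbors
    p = mesh.vertices
    eps = mesh.reference_eps
    target_foot = (
        eps[:, 0, None] * p[nbrs[:, 0]]
        + eps[:, 1, None] * p[nbrs[:, 1]]
        + eps[:, 2, None] * p[nbrs[:, 2]]
    )
    avg = mesh.neighborhood_average(params.smoothness_scale)
    phi_target = avg @ geo["phi"]
    d = np.linalg.norm(target_foot - geo["C"], axis=1)
    L = _elevation(geo["r"], d, phi_target)
    force = target_foot + L[:, None] * geo["n"] - p
    force[geo["degenerate"]] = 0.0
    return force


def internal_force(mesh: SimplexMesh, i: int, params: StageParameters) -> np.ndarray:
    """Internal force at vertex `i` (see :func:`internal_forces`)."""
    return internal_forces(mesh, params)[i]


# ---------------------------------------------------------------------------
# Image search machinery shared by gradient and collision forces
# ---------------------------------------------------------------------------

_BALL_CACHE: dict[int, np.ndarray] = {}


def _ball_offsets(radius: int) -> np.ndarray:
    """Integer offsets with |o| <= radius, ordered by (|o|^2, flat order)."""
    if radius not in _BALL_CACHE:
        r = int(radius)
        ax = np.arange(-r, r + 1)
        ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
        off = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
        d2 = np.einsum("ij,ij->i", off, off)
        off = off[d2 <= r * r]
        _BALL_CACHE[radius] = off
    return _BALL_CACHE[radius]


def _search_maximum(
    volume: ScalarVolume,
    positions: np.ndarray,
    radius: int,
    active: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
):
    """For each position, the voxel of maximal value within `radius` voxels.

    Ties in value are broken by smallest Euclidean distance between voxel
    center and the (continuous) position, then by lowest flat voxel index.
    `exclude` (same-shape boolean array) removes voxels from the search —
    used to keep a mesh from chasing edges inside another mesh's territory.
    Returns (best_world_point (n,3), best_value (n,), found (n,) bool);
    positions outside the grid, or inactive rows, are not-found.
    """
    n = len(positions)
    found = np.zeros(n, dtype=bool)
    best_pt = np.zeros((n, 3))
    best_val = np.full(n, -np.inf)
    if active is None:
        active = np.ones(n, dtype=bool)
    v0 = volume.nearest_voxel(positions)
    active = active & volume.in_bounds(v0)
    if not np.any(active):
        return best_pt, best_val, found
    idx_a = np.flatnonzero(active)
    off = _ball_offsets(radius)
    cand = v0[idx_a][:, None, :] + off[None, :, :]  # (m, K, 3)
    shape = np.asarray(volume.shape)
    ok = np.all((cand >= 0) & (cand < shape), axis=2)
    cc = np.clip(cand, 0, shape - 1)
    vals = volume.values[cc[..., 0], cc[..., 1], cc[..., 2]].astype(float)
    vals[~ok] = -np.inf
    if exclude is not None:
        vals[exclude[cc[..., 0], cc[..., 1], cc[..., 2]] & ok] = -np.inf
    vmax = vals.max(axis=1)
    has = np.isfinite(vmax)
    # tie-break 1: distance from voxel center to the continuous position
    centers = volume.voxel_to_world(cand)
    delta = centers - positions[idx_a][:, None, :]
    d2 = np.einsum("mkj,mkj->mk", delta, delta)
    d2_masked = np.where(vals == vmax[:, None], d2, np.inf)
    d2_min = d2_masked.min(axis=1)
    # tie-break 2: lowest flat voxel index
    flat = (cand[..., 0] * shape[1] + cand[..., 1]) * shape[2] + cand[..., 2]
    flat_masked = np.where(d2_masked == d2_min[:, None], flat, np.iinfo(np.int64).max)
    pick = flat_masked.argmin(axis=1)
    sel = centers[np.arange(len(idx_a)), pick]
    best_pt[idx_a] = sel
    best_val[idx_a] = vmax
    found[idx_a] = has
    return best_pt, best_val, found


def _along_normal(points, positions, normals, cap: float) -> np.ndarray:
    """Displacement toward `points`, projected onto the vertex normals and
    capped at `cap` mm (one voxel) so the pull saturates at a unit step."""
    s = np.einsum("ij,ij->i", points - positions, normals)
    s = np.clip(s, -cap, cap)
    return s[:, None] * normals


def _subvoxel_refine(
    volume: ScalarVolume, targets: np.ndarray, positions: np.ndarray,
    normals: np.ndarray, h: float,
) -> np.ndarray:
    """Quadratic sub-voxel localization of the search maximum.

    The voxel-center target is shifted along the vertex normal by the vertex
    of the parabola through the interpolated values one voxel either side —
    standard sub-voxel edge localization, removing the half-voxel
    quantization bias of an argmax over voxel centers."""
    s0 = np.einsum("ij,ij->i", targets - positions, normals)
    probe = positions[:, None, :] + (s0[:, None] + np.array([-1.0, 0.0, 1.0]) * h)[
        :, :, None
    ] * normals[:, None, :]
    g = volume.sample_linear(probe.reshape(-1, 3)).reshape(-1, 3)
    denom = g[:, 0] - 2.0 * g[:, 1] + g[:, 2]
    delta = np.where(
        np.abs(denom) > 1e-12, 0.5 * (g[:, 0] - g[:, 2]) / np.where(denom == 0, 1, denom), 0.0
    )
    delta = np.clip(delta, -0.5, 0.5) * h
    return targets + delta[:, None] * normals


# ---------------------------------------------------------------------------
# External forces
# ---------------------------------------------------------------------------


def gradient_forces(
    gradmag: ScalarVolume,
    mesh: SimplexMesh,
    params: StageParameters,
    curvature_comp: float = 0.0,
    foreign: BinaryMask | None = None,
) -> np.ndarray:
    """Normal-direction pull toward the strongest-gradient voxel within
    ``gradient_search_radius`` voxels of each vertex; zero where no voxel
    exceeds the gradient floor or the vertex is outside the volume.

    `curvature_comp` (mm^2; typically the square of the gradient-smoothing
    sigma) shifts the localized edge outward by ``curvature_comp * H`` at
    convex vertices: Gaussian smoothing moves the gradient ridge of a curved
    step inward by about sigma^2 times the mean curvature, and this undoes
    that bias."""
    geo = simplex_geometry(mesh)
    pts, vals, found = _search_maximum(
        gradmag,
        mesh.vertices,
        params.gradient_search_radius,
        exclude=None if foreign is None else foreign.values.astype(bool),
    )
    act = found & (vals > params.gradient_floor)
    force = np.zeros_like(mesh.vertices)
    if np.any(act):
        h = float(np.mean(gradmag.spacing))
        tgt = _subvoxel_refine(
            gradmag, pts[act], mesh.vertices[act], geo["n"][act], h
        )
        if curvature_comp > 0.0:
            H = np.sin(geo["phi"][act]) / np.maximum(geo["r"][act], 1e-12)
            shift = np.clip(curvature_comp * np.maximum(H, 0.0), 0.0, 0.5 * h)
            tgt = tgt + shift[:, None] * geo["n"][act]
        force[act] = _along_normal(tgt, mesh.vertices[act], geo["n"][act], h)
    return force


def gradient_force(
    gradmag: ScalarVolume, mesh: SimplexMesh, i: int, params: StageParameters
) -> np.ndarray:
    return gradient_forces(gradmag, mesh, params)[i]


def edge_forces(
    image: ScalarVolume, mesh: SimplexMesh, params: StageParameters
) -> np.ndarray:
    """Pull toward the highest-intensity voxel along each vertex's normal
    line, sampled at one-voxel steps within the search radius; the search
    truncates at the volume boundary."""
    geo = simplex_geometry(mesh)
    n = geo["n"]
    p = mesh.vertices
    h = float(np.mean(image.spacing))
    R = params.gradient_search_radius
    # sample order: |s| ascending, negative side first at equal |s|
    steps = np.concatenate([[0.0], np.ravel([[-s, s] for s in range(1, R + 1)])])
    samples = p[:, None, :] + steps[None, :, None] * h * n[:, None, :]
    idx = image.nearest_voxel(samples.reshape(-1, 3)).reshape(len(p), len(steps), 3)
    shape = np.asarray(image.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=2)
    cc = np.clip(idx, 0, shape - 1)
    vals = image.values[cc[..., 0], cc[..., 1], cc[..., 2]].astype(float)
    vals[~ok] = -np.inf
    best = vals.argmax(axis=1)  # first maximum = smallest |s|, negative first
    s_best = np.clip(steps[best], -1.0, 1.0)  # saturate at a one-voxel step
    has = np.isfinite(vals[np.arange(len(p)), best])
    force = (s_best * h)[:, None] * n
    force[~has] = 0.0
    return force


def edge_force(
    image: ScalarVolume, mesh: SimplexMesh, i: int, params: StageParameters
) -> np.ndarray:
    return edge_forces(image, mesh, params)[i]


def balloon_forces(
    classified: ScalarVolume, mesh: SimplexMesh, params: StageParameters
) -> np.ndarray:
    """Indicator-gated inflation: B(I(p)) * n with B = 1 iff the classified
    value at the vertex (nearest-neighbour lookup) lies in
    [t_low, t_high].  The magnitude is one voxel (mean spacing) so the
    update scale is resolution-consistent."""
    geo = simplex_geometry(mesh)
    vals = classified.sample_nearest(mesh.vertices, outside=np.nan)
    B = (vals >= params.t_low) & (vals <= params.t_high)
    B = np.where(np.isnan(vals), False, B)
    h = float(np.mean(classified.spacing))
    return np.where(B[:, None], h * geo["n"], 0.0)


def balloon_force(
    classified: ScalarVolume, mesh: SimplexMesh, i: int, params: StageParameters
) -> np.ndarray:
    return balloon_forces(classified, mesh, params)[i]


def collision_forces(
    collision_energy: BinaryMask,
    gradmag: ScalarVolume,
    mesh: SimplexMesh,
    params: StageParameters,
) -> np.ndarray:
    """Boundary-seeking force at vertices that have entered foreign
    territory.

    The collision energy image gates the force: vertices whose containing
    voxel has energy 0 feel nothing.  Gated vertices run the same
    normal-projected gradient search as the gradient force but over the
    (larger) ``collision_search_radius`` neighbourhood, under the
    assumption that the true inter-object boundary lies close to where the
    simultaneously-inflating surfaces met."""
    energy_at = collision_energy.sample_nearest(mesh.vertices, outside=0.0)
    gate = energy_at > 0.5
    force = np.zeros_like(mesh.vertices)
    if not np.any(gate):
        return force
    geo = simplex_geometry(mesh)
    # the boundary sought cannot lie inside foreign territory: the energy
    # image thresholds the search domain as well as gating the force
    pts, vals, found = _search_maximum(
        gradmag,
        mesh.vertices,
        params.collision_search_radius,
        active=gate,
        exclude=collision_energy.values.astype(bool),
    )
    act = found & (vals > params.gradient_floor)
    if np.any(act):
        h = float(np.mean(gradmag.spacing))
        tgt = _subvoxel_refine(
            gradmag, pts[act], mesh.vertices[act], geo["n"][act], h
        )
        force[act] = _along_normal(tgt, mesh.vertices[act], geo["n"][act], h)
    return force


def collision_force(
    collision_energy: BinaryMask,
    gradmag: ScalarVolume,
    mesh: SimplexMesh,
    i: int,
    params: StageParameters,
) -> np.ndarray:
    return collision_forces(collision_energy, gradmag, mesh, params)[i]


# ---------------------------------------------------------------------------
# Motion update
# ---------------------------------------------------------------------------


def external_forces_sum(
    params: StageParameters,
    f_gradient: np.ndarray,
    f_edge: np.ndarray,
    f_balloon: np.ndarray,
    f_collision: np.ndarray,
    balloon_weight: float | None = None,
) -> np.ndarray:
    """Weighted external force sum; `balloon_weight` overrides the stage
    weight (the collision latch zeroes it per mesh)."""
    wb = params.w_balloon if balloon_weight is None else balloon_weight
    return (
        params.w_gradient * f_gradient
        + params.w_edge * f_edge
        + wb * f_balloon
        + params.w_collision * f_collision
    )


def step(
    mesh: SimplexMesh,
    total_forces: np.ndarray,
    params: StageParameters,
    max_step: float | None = None,
) -> SimplexMesh:
    """One time step of the equation of motion, in place.

    ``p_{t+1} = p_t + (1 - gamma)(p_t - p_{t-1}) + total_forces`` where
    `total_forces` already contains the weighted internal + external sum.
    When `max_step` (mm) is given, the per-vertex displacement norm is
    capped at it — a numerical guard keeping the motion stable once the
    mesh edge length drops below the image-force step size.  Updates
    ``prev_positions`` and returns the mesh.
    """
    total_forces = np.asarray(total_forces, dtype=float)
    if not np.all(np.isfinite(total_forces)):
        bad = int(np.argwhere(~np.isfinite(total_forces))[0][0])
        raise ForceError(f"non-finite total force at vertex {bad}")
    p = mesh.vertices
    delta = (1.0 - params.gamma) * (p - mesh.prev_positions) + total_forces
    if max_step is not None:
        nrm = np.linalg.norm(delta, axis=1, keepdims=True)
        delta = delta * np.minimum(1.0, max_step / np.maximum(nrm, 1e-300))
    mesh.prev_positions = p.copy()
    mesh.vertices = p + delta
    return mesh
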