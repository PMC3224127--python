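"""Synthetic 3-D fixture: a gel-filled tube containing touching ellipsoidal
objects, with exact ground truth.

The generator emulates the structure that makes this segmentation problem
hard: object and gel intensity distributions that overlap, a smooth
multiplicative bias field standing in for intensity inhomogeneity across
the gel, additive acquisition noise, several objects that touch each other
and the tube wall, and a dark exterior background.  Objects are plain
ellipsoids — the method's acknowledged failure modes on thin appendages
(paws, tails) are outside what the phantom is meant to exercise, though an
optional appendage mode adds a thin protrusion for qualitative demos.

Default intensities (gel 70 +/- 6, object 95 +/- 16, background 10 +/- 2,
bias +/-20%, noise SD 2) give histograms with substantial object/gel
overlap so that global thresholding fails, while the texture (local SD)
still separates the classes for the supervised classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import TrainingSet
from .volume import BinaryMask, ScalarVolume


class PhantomSpecError(ValueError):
    """Raised for geometrically impossible phantom specifications."""


@dataclass
class PhantomSpec:
    """Geometry and statistics of one synthetic tube."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tube_center_xy: tuple[float, float] = (31.5, 31.5)
    tube_radius: float = 19.4
    tube_z_range: tuple[float, float] = (4.0, 59.0)
    centers: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [23.5, 23.5, 31.5],
                [39.5, 23.5, 31.5],
                [39.5, 39.5, 31.5],
                [23.5, 39.5, 31.5],
            ]
        )
    )
    semi_axes: np.ndarray = field(
        default_factory=lambda: np.array([[8.0, 8.0, 10.0]] * 4)
    )
    rotations: np.ndarray | None = None  # (n, 3, 3) world<-object, default identity
    object_mean: float = 95.0
    object_sd: float = 16.0
    gel_mean: float = 70.0
    gel_sd: float = 6.0
    background_mean: float = 10.0
    background_sd: float = 2.0
    bias_amplitude: float = 0.2
    noise_sd: float = 2.0
    n_training_per_class: int = 25
    appendages: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.semi_axes = np.atleast_2d(np.asarray(self.semi_axes, dtype=float))
        if len(self.centers) != len(self.semi_axes):
            raise PhantomSpecError("centers and semi_axes must have equal length")
        if np.any(self.semi_axes <= 0):
            raise PhantomSpecError("semi-axes must be positive")

    @property
    def n_objects(self) -> int:
        return len(self.centers)


def default_tube(n_objects: int) -> PhantomSpec:
    """Deterministic layered layout: up to 4 objects per layer, consecutive
    objects in a layer touching, stacked layers touching, outermost extent
    touching the tube wall.  The grid grows along z with the layer count.
    """
    if not 1 <= n_objects <= 32:
        raise PhantomSpecError(f"n_objects must be in [1, 32], got {n_objects}")
    a, c = 8.0, 10.0  # xy and z semi-axes
    n_layers = (n_objects + 3) // 4
    nz = max(64, int(2 * c * n_layers + 16))
    # the 2x2 layer pattern sits slightly off the tube axis so that exactly
    # one object per layer is tangent to the wall while the others keep a
    # few voxels of gel clearance
    shift = 2.5
    cx = cy = 31.5 + shift
    offsets = np.array([[-a, -a], [a, -a], [a, a], [-a, a]])  # consecutive touch
    centers = []
    z0 = (nz - 1) / 2.0 - c * (n_layers - 1)
    for k in range(n_objects):
        layer, pos = divmod(k, 4)
        ox, oy = offsets[pos]
        centers.append([cx + ox, cy + oy, z0 + layer * 2 * c])
    centers = np.asarray(centers)
    # wall tangent to the outermost ellipsoid (the (+,+) position)
    tube_radius = float(np.hypot(a + shift, a + shift) + a)
    return PhantomSpec(
        shape=(64, 64, nz),
        tube_z_range=(4.0, nz - 5.0),
        centers=centers,
        semi_axes=np.array([[a, a, c]] * n_objects),
        tube_radius=tube_radius,
    )


def _ellipsoid_inside(spec: PhantomSpec, k: int, pts: np.ndarray) -> np.ndarray:
    """Strict-interior test of world points against object k."""
    d = pts - spec.centers[k]
    if spec.rotations is not None:
        d = d @ spec.rotations[k]  # world -> object frame
    q = (d / spec.semi_axes[k]) ** 2
    return q.sum(axis=-1) < 1.0


def _bias_field(spec: PhantomSpec, gx, gy, gz) -> np.ndarray:
    """Smooth multiplicative field: 1 + amplitude * mean of three separable
    low-frequency cosine modes, phases drawn from the spec seed."""
    rng = np.random.default_rng(spec.random_seed + 101)
    ph = rng.uniform(0, 2 * np.pi, size=6)
    nx, ny, nz = spec.shape
    m1 = np.cos(2 * np.pi * gx / nx + ph[0]) * np.cos(2 * np.pi * gy / ny + ph[1])
    m2 = np.cos(2 * np.pi * gy / ny + ph[2]) * np.cos(2 * np.pi * gz / nz + ph[3])
    m3 = np.cos(2 * np.pi * gz / nz + ph[4]) * np.cos(2 * np.pi * gx / nx + ph[5])
    return 1.0 + spec.bias_amplitude * (m1 + m2 + m3) / 3.0


def generate(
    spec: PhantomSpec,
) -> tuple[ScalarVolume, list[BinaryMask], np.ndarray, TrainingSet]:
    """Generate (volume, truth masks, seeds, training set) from a spec.

    The volume is ``bias * class_texture + noise``: object and gel voxels
    draw from their class Gaussians, the exterior background is distinctly
    darker.  Truths are the exact voxelized ellipsoids (strict interior);
    seeds are the object centers; training points are drawn uniformly from
    object and gel voxels.  Fully deterministic given ``spec.random_seed``.
    """
    nx, ny, nz = spec.shape
    spacing = np.asarray(spec.spacing, dtype=float)
    gx, gy, gz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    wx = gx * spacing[0]
    wy = gy * spacing[1]
    wz = gz * spacing[2]
    pts = np.stack([wx, wy, wz], axis=-1)

    cx, cy = spec.tube_center_xy
    tube = (
        ((wx - cx) ** 2 + (wy - cy) ** 2 <= spec.tube_radius**2)
        & (wz >= spec.tube_z_range[0])
        & (wz <= spec.tube_z_range[1])
    )

    truths = []
    object_any = np.zeros(spec.shape, dtype=bool)
    for k in range(spec.n_objects):
        inside = _ellipsoid_inside(spec, k, pts)
        if spec.appendages and k == 0:
            # thin protrusion toward -z: qualitative demos only
            r_app = 1.5
            z0 = spec.centers[k][2] - spec.semi_axes[k][2]
            app = (
                ((wx - spec.centers[k][0]) ** 2 + (wy - spec.centers[k][1]) ** 2 < r_app**2)
                & (wz > z0 - 6.0)
                & (wz <= z0 + 1.0)
            )
            inside = inside | app
        overlap = inside & object_any
        if np.any(overlap):
            raise PhantomSpecError(
                f"object {k} overlaps an earlier object in "
                f"{int(overlap.sum())} voxels (beyond tangency tolerance)"
            )
        if not np.all(tube[inside]):
            raise PhantomSpecError(f"object {k} extends outside the tube region")
        object_any |= inside
        truths.append(inside)

    gel = tube & ~object_any

    rng = np.random.default_rng(spec.random_seed)
    values = rng.normal(spec.background_mean, spec.background_sd, spec.shape)
    values[gel] = rng.normal(spec.gel_mean, spec.gel_sd, int(gel.sum()))
    values[object_any] = rng.normal(
        spec.object_mean, spec.object_sd, int(object_any.sum())
    )
    values *= _bias_field(spec, gx, gy, gz)
    values += rng.normal(0.0, spec.noise_sd, spec.shape)

    volume = ScalarVolume(values, spacing, np.zeros(3))
    truth_masks = [
        BinaryMask.from_volume_grid(volume, t.astype(np.uint8)) for t in truths
    ]
    seeds = spec.centers.copy() * 1.0  # already world coordinates (origin 0)

    # emulate manual training-point selection: representative voxels away
    # from class boundaries (a window half-width inside the class region),
    # as a user clicking homogeneous territory would pick
    from scipy import ndimage

    margin = 3
    obj_core = ndimage.binary_erosion(object_any, iterations=margin)
    gel_core = ndimage.binary_erosion(gel, iterations=margin)
    obj_idx = np.argwhere(obj_core if obj_core.sum() >= spec.n_training_per_class else object_any)
    gel_idx = np.argwhere(gel_core if gel_core.sum() >= spec.n_training_per_class else gel)
    n_tr = spec.n_training_per_class
    if len(obj_idx) < n_tr or len(gel_idx) < n_tr:
        raise PhantomSpecError("phantom too small to draw the training set")
    training = TrainingSet(
        object_coords=obj_idx[rng.choice(len(obj_idx), n_tr, replace=False)],
        gel_coords=gel_idx[rng.choice(len(gel_idx), n_tr, replace=False)],
    )
    return volume, truth_masks, seeds, training


def tube_truth_mask(spec: PhantomSpec, volume: ScalarVolume) -> BinaryMask:
    """Exact tube-region mask (for validating the histogram tube mask)."""
    nx, ny, nz = spec.shape
    spacing = np.asarray(spec.spacing, dtype=float)
    gx, gy, gz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    wx, wy, wz = gx * spacing[0], gy * spacing[1], gz * spacing[2]
    cx, cy = spec.tube_center_xy
    tube = (
        ((wx - cx) ** 2 + (wy - cy) ** 2 <= spec.tube_radius**2)
        & (wz >= spec.tube_z_range[0])
        & (wz <= spec.tube_z_range[1])
    )
    return BinaryMask.from_volume_grid(volume, tube.astype(np.uint8))
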