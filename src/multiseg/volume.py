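"""Voxel-grid containers shared by every stage of the pipeline.

A :class:`ScalarVolume` is a 3-D scalar field on a regular grid with
anisotropic spacing and a world origin; a :class:`BinaryMask` is the same
grid restricted to {0, 1} values.  Meshes live in world (mm) coordinates;
the grid uses a 0-based voxel-center convention, so voxel index ``(i, j, k)``
sits at world position ``origin + spacing * (i, j, k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Two volumes that must share a grid (shape, spacing, origin) do not."""


@dataclass
class ScalarVolume:
    """A 3-D scalar field on a regular, axis-aligned grid.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)``.
    spacing
        Voxel size per axis in mm; strictly positive.
    origin
        World coordinate of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    # -- grid geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_grid(self, other: "ScalarVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "ScalarVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world (mm) coordinates to continuous voxel coordinates."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world coordinates."""
        return np.asarray(indices, dtype=float) * self.spacing + self.origin

    def nearest_voxel(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel index containing each world point (round-to-nearest)."""
        return np.rint(self.world_to_voxel(points)).astype(np.int64)

    def in_bounds(self, idx: np.ndarray) -> np.ndarray:
        """Boolean array: which integer voxel indices fall inside the grid."""
        idx = np.asarray(idx)
        shape = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shape), axis=-1)

    def sample_nearest(self, points: np.ndarray, outside=0.0) -> np.ndarray:
        """Nearest-neighbour lookup at world points; `outside` past the grid."""
        pts = np.atleast_2d(points)
        idx = self.nearest_voxel(pts)
        ok = self.in_bounds(idx)
        out = np.full(len(pts), outside, dtype=float)
        if np.any(ok):
            i = idx[ok]
            out[ok] = self.values[i[:, 0], i[:, 1], i[:, 2]]
        return out if np.asarray(points).ndim > 1 else out[0]

    def sample_linear(self, points: np.ndarray, outside=0.0) -> np.ndarray:
        """Trilinear interpolation at world points; `outside` past the grid."""
        from scipy import ndimage

        pts = np.atleast_2d(points)
        vox = self.world_to_voxel(pts)
        vals = ndimage.map_coordinates(
            self.values.astype(float), vox.T, order=1, mode="constant", cval=outside
        )
        return vals if np.asarray(points).ndim > 1 else vals[0]

    def like(self, values: np.ndarray) -> "ScalarVolume":
        """New volume with the same grid and different values."""
        return ScalarVolume(values, self.spacing.copy(), self.origin.copy())


class BinaryMask(ScalarVolume):
    """A {0,1}-valued volume on the same grid convention as ScalarVolume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        v = np.asarray(self.values)
        if not np.isin(np.unique(v), (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = v.astype(np.uint8)

    @property
    def volume_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return float(self.values.sum() * np.prod(self.spacing))

    def like_mask(self, values: np.ndarray) -> "BinaryMask":
        return BinaryMask(values, self.spacing.copy(), self.origin.copy())

    @classmethod
    def from_volume_grid(cls, grid: ScalarVolume, values: np.ndarray) -> "BinaryMask":
        return cls(values, grid.spacing.copy(), grid.origin.copy())
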