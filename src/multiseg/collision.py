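"""Collision detection between simultaneously deforming meshes.

Rather than testing mesh-mesh intersections geometrically, each mesh gets a
*collision energy image*: the voxelwise exclusive-or of the rasterized
binary masks of all the *other* meshes.  A vertex whose containing voxel
has energy 1 has entered foreign territory; the energy image both flags the
collision and gates the collision force.  XOR (not union) is implemented
exactly as specified — where two other masks themselves overlap, their
contributions cancel — with an optional union mode for robustness
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np

from .mesh import SimplexMesh
from .volume import BinaryMask


@dataclass
class CollisionEnergySet:
    """Rasterized masks M_i and their collision energies C_i = XOR_{j != i} M_j."""

    masks: list
    energies: list
    iteration_stamp: int = 0


def build_energy_images(
    masks: list[BinaryMask], mode: str = "xor", iteration_stamp: int = 0
) -> CollisionEnergySet:
    """Collision energy image per mesh from the current binary masks.

    ``C_i`` combines all masks except ``M_i``: voxelwise XOR by default
    (``mode='union'`` uses OR instead).  A single mesh gets an all-zero
    energy.  Uses the identity ``XOR_{j != i} M_j = (XOR_j M_j) XOR M_i`` so
    the whole set costs O(N) combines.
    """
    if len(masks) < 1:
        raise ValueError("need at least one mask")
    if mode not in ("xor", "union"):
        raise ValueError(f"mode must be 'xor' or 'union', got {mode!r}")
    first = masks[0]
    for m in masks[1:]:
        first.require_same_grid(m)
    vals = [m.values.astype(np.uint8) for m in masks]
    if mode == "xor":
        total = reduce(np.bitwise_xor, vals)
        energies = [first.like_mask(total ^ v) for v in vals]
    else:
        energies = [
            first.like_mask(
                reduce(np.bitwise_or, [v for j, v in enumerate(vals) if j != i])
                if len(vals) > 1
                else np.zeros_like(vals[0])
            )
            for i in range(len(vals))
        ]
    return CollisionEnergySet(list(masks), energies, iteration_stamp)


def detect_collisions(mesh_i: SimplexMesh, energy_i: BinaryMask) -> np.ndarray:
    """Indices of vertices whose containing voxel has collision energy 1.

    Vertices outside the grid are treated as non-colliding (the tube mask,
    not the collision machinery, owns the out-of-volume case).
    """
    idx = energy_i.nearest_voxel(mesh_i.vertices)
    ok = energy_i.in_bounds(idx)
    hit = np.zeros(mesh_i.n_vertices, dtype=bool)
    if np.any(ok):
        i = idx[ok]
        hit[ok] = energy_i.values[i[:, 0], i[:, 1], i[:, 2]] > 0
    return np.flatnonzero(hit)
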