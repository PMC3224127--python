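"""Histogram-derived mask of the sample tube, and the hard displacement
constraint that keeps every mesh vertex inside it.

The container (tube) is much brighter than the surrounding background, so
the intensity histogram shows a dominant background peak at low intensity
followed by a dip before the tube intensities.  The lower threshold is the
mean intensity of the voxels in the bin holding the first local minimum
after the first highest peak; the upper threshold is simply the data
maximum.  Thresholding, keeping the largest connected component and filling
internal holes yields a solid tube mask that no vertex displacement may
leave.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, ScalarVolume

logger = logging.getLogger(__name__)


class ThresholdError(RuntimeError):
    """No local minimum after the histogram peak; manual thresholds needed."""


@dataclass
class HistogramThresholds:
    """Tube-mask thresholds plus the histogram they came from."""

    t_low: float
    t_high: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.t_low >= self.t_high:
            raise ValueError(f"need t_low < t_high, got {self.t_low} >= {self.t_high}")


def find_thresholds(image: ScalarVolume, nbins: int = 256) -> HistogramThresholds:
    """Locate the tube thresholds on the intensity histogram.

    The *first highest peak* is the lowest-intensity bin attaining the
    maximum count; scanning toward higher intensities, the first bin whose
    count is <= both neighbours is the local minimum.  ``t_low`` is the mean
    intensity of the voxels falling in that bin; ``t_high`` the data
    maximum.
    """
    if nbins < 8:
        raise ValueError(f"nbins must be >= 8, got {nbins}")
    data = image.values.ravel()
    counts, edges = np.histogram(data, bins=nbins)
    peak = int(np.argmax(counts))  # argmax takes the lowest-intensity tie
    minimum = None
    for b in range(peak + 1, nbins - 1):
        if counts[b] <= counts[b - 1] and counts[b] <= counts[b + 1]:
            minimum = b
            break
    if minimum is None:
        raise ThresholdError(
            "histogram has no local minimum after the first highest peak; "
            "supply manual tube thresholds"
        )
    lo, hi = edges[minimum], edges[minimum + 1]
    # right edge inclusive only for the last bin, matching np.histogram
    if minimum == nbins - 1:
        members = data[(data >= lo) & (data <= hi)]
    else:
        members = data[(data >= lo) & (data < hi)]
    t_low = float(members.mean()) if len(members) else float((lo + hi) / 2.0)
    t_high = float(data.max())
    return HistogramThresholds(t_low, t_high, edges, counts)


def make_tube_mask(
    image: ScalarVolume,
    thresholds: HistogramThresholds,
    cleanup: bool = True,
) -> BinaryMask:
    """Binary-threshold the image at [t_low, t_high]; with `cleanup`, keep
    the largest 26-connected component and fill internal holes."""
    raw = (image.values >= thresholds.t_low) & (image.values <= thresholds.t_high)
    if not np.any(raw):
        raise ThresholdError("tube mask empty after thresholding")
    if cleanup:
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        labels, n = ndimage.label(raw, structure=structure)
        if n > 1:
            sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
            raw = labels == (1 + int(np.argmax(sizes)))
        raw = ndimage.binary_fill_holes(raw)
    return BinaryMask.from_volume_grid(image, raw.astype(np.uint8))


def clamp_displacement(
    point_old: np.ndarray, point_new: np.ndarray, mask: BinaryMask
) -> np.ndarray:
    """Accept `point_new` only if its containing voxel has mask = 1; else
    return `point_old` (zero displacement).  Diagnostic if even the old
    point is outside."""
    new_ok = mask.sample_nearest(point_new, outside=0.0) > 0.5
    if new_ok:
        return np.asarray(point_new, dtype=float)
    if mask.sample_nearest(point_old, outside=0.0) < 0.5:
        logger.warning("clamp_displacement: previous point %s already outside the tube mask",
                       np.asarray(point_old))
    return np.asarray(point_old, dtype=float)


def clamp_displacements(
    old_positions: np.ndarray, new_positions: np.ndarray, mask: BinaryMask
) -> np.ndarray:
    """Vectorized :func:`clamp_displacement` over all vertices."""
    idx = mask.nearest_voxel(new_positions)
    ok = mask.in_bounds(idx)
    inside = np.zeros(len(new_positions), dtype=bool)
    if np.any(ok):
        i = idx[ok]
        inside[ok] = mask.values[i[:, 0], i[:, 1], i[:, 2]] > 0
    return np.where(inside[:, None], new_positions, old_positions)
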