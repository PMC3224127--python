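"""Segmentation agreement measures: confusion counts, Cohen's kappa,
specificity, accuracy, and Dice overlap.

By convention the evaluation region defaults to the whole grid; engine-level
evaluation restricts to the tube mask so the vast trivially-agreeing
exterior background does not inflate accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import BinaryMask


class MetricError(ValueError):
    """Raised when a measure is undefined for the given counts."""


@dataclass
class ConfusionCounts:
    """Voxel counts of a test mask against a truth mask over a region."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def confusion(
    test: BinaryMask, truth: BinaryMask, region: BinaryMask | None = None
) -> ConfusionCounts:
    """Voxelwise confusion counts within `region` (whole grid if None)."""
    test.require_same_grid(truth)
    t = test.values.astype(bool)
    g = truth.values.astype(bool)
    if region is not None:
        test.require_same_grid(region)
        r = region.values.astype(bool)
        t, g = t[r], g[r]
    return ConfusionCounts(
        tp=int(np.count_nonzero(t & g)),
        fp=int(np.count_nonzero(t & ~g)),
        fn=int(np.count_nonzero(~t & g)),
        tn=int(np.count_nonzero(~t & ~g)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(tp + tn) / n."""
    if c.n == 0:
        raise MetricError("accuracy undefined for empty region")
    return (c.tp + c.tn) / c.n


def specificity(c: ConfusionCounts) -> float:
    """tn / (tn + fp)."""
    if c.tn + c.fp == 0:
        raise MetricError("specificity undefined: no truth-negative voxels")
    return c.tn / (c.tn + c.fp)


def kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) with expected agreement p_e
    from the marginals.  Undefined (error) when both raters are constant."""
    n = c.n
    if n == 0:
        raise MetricError("kappa undefined for empty region")
    p_o = (c.tp + c.tn) / n
    p_pos_test = (c.tp + c.fp) / n
    p_pos_truth = (c.tp + c.fn) / n
    p_e = p_pos_test * p_pos_truth + (1 - p_pos_test) * (1 - p_pos_truth)
    if abs(1.0 - p_e) < 1e-15:
        raise MetricError("kappa undefined: both raters constant (p_e = 1)")
    return (p_o - p_e) / (1.0 - p_e)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 for two empty masks."""
    a.require_same_grid(b)
    av = a.values.astype(bool)
    bv = b.values.astype(bool)
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(av & bv)) / denom
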