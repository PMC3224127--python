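"""Supervised two-class Bayesian voxel classification (object vs gel).

Each voxel is described by a two-feature vector — its intensity and the
standard deviation over a small centered window (a texture measure) — and a
Gaussian class-conditional density is fitted per class from user-picked
training coordinates.  Voxels are assigned the maximum-a-posteriori label,
encoded as +1.0 (object) / -1.0 (gel) so the balloon force's pass band
``[-0.99, 1.0]`` admits exactly the object-labelled voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ScalarVolume

logger = logging.getLogger(__name__)

OBJECT_LABEL = "object"
GEL_LABEL = "gel"
OBJECT_VALUE = 1.0
GEL_VALUE = -1.0

_RIDGE = 1e-6


class TrainingSetError(ValueError):
    """Raised for invalid training data (too few points, out-of-volume...)."""


@dataclass
class TrainingSet:
    """Labelled voxel coordinates for the two classes (0-based indices)."""

    object_coords: np.ndarray  # (n_obj, 3) int
    gel_coords: np.ndarray  # (n_gel, 3) int

    def __post_init__(self) -> None:
        self.object_coords = np.atleast_2d(np.asarray(self.object_coords, dtype=np.int64))
        self.gel_coords = np.atleast_2d(np.asarray(self.gel_coords, dtype=np.int64))
        for name, c in (("object", self.object_coords), ("gel", self.gel_coords)):
            if c.shape[0] < 2 or c.shape[1] != 3:
                raise TrainingSetError(
                    f"class '{name}' needs >= 2 three-dimensional points, got shape {c.shape}"
                )

    def validate_against(self, volume: ScalarVolume) -> None:
        shape = np.asarray(volume.shape)
        for name, c in (("object", self.object_coords), ("gel", self.gel_coords)):
            bad = ~np.all((c >= 0) & (c < shape), axis=1)
            if np.any(bad):
                raise TrainingSetError(
                    f"class '{name}': training coordinate {c[bad][0].tolist()} "
                    f"outside volume of shape {tuple(volume.shape)}"
                )


@dataclass
class ClassModel:
    """Per-class Gaussian feature model: centroid, covariance, prior."""

    means: np.ndarray  # (2, n_feat) — rows: object, gel
    covariances: np.ndarray  # (2, n_feat, n_feat)
    priors: np.ndarray  # (2,)


def local_sd_volume(image: ScalarVolume, window: int = 5) -> ScalarVolume:
    """Per-voxel standard deviation over a centered cubic window.

    Edge voxels use the truncated window (statistics over the voxels that
    actually fall inside the volume).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if any(window > s for s in image.shape):
        raise ValueError(f"window {window} larger than volume {image.shape}")
    x = image.values.astype(np.float64)
    size = float(window**3)
    ones = np.ones_like(x)
    count = ndimage.uniform_filter(ones, window, mode="constant", cval=0.0) * size
    s1 = ndimage.uniform_filter(x, window, mode="constant", cval=0.0) * size
    s2 = ndimage.uniform_filter(x * x, window, mode="constant", cval=0.0) * size
    mean = s1 / count
    var = np.maximum(s2 / count - mean**2, 0.0)
    return image.like(np.sqrt(var))


def _features_at(image: ScalarVolume, sd: ScalarVolume, coords: np.ndarray) -> np.ndarray:
    i, j, k = coords[:, 0], coords[:, 1], coords[:, 2]
    return np.stack([image.values[i, j, k], sd.values[i, j, k]], axis=1).astype(float)


def fit(image: ScalarVolume, sd_volume: ScalarVolume, training: TrainingSet) -> ClassModel:
    """Fit per-class Gaussians to (intensity, local SD) at the training
    coordinates; priors proportional to training counts.  A singular sample
    covariance is ridge-regularized (with a diagnostic)."""
    image.require_same_grid(sd_volume)
    training.validate_against(image)
    means = []
    covs = []
    counts = []
    for name, coords in (
        (OBJECT_LABEL, training.object_coords),
        (GEL_LABEL, training.gel_coords),
    ):
        f = _features_at(image, sd_volume, coords)
        mu = f.mean(axis=0)
        cov = np.cov(f, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        scale = max(np.trace(cov) / cov.shape[0], 1.0)
        if np.linalg.matrix_rank(cov) < cov.shape[0] or np.linalg.cond(cov) > 1e10:
            logger.warning(
                "class '%s': singular/ill-conditioned covariance, ridge-regularizing",
                name,
            )
            cov = cov + _RIDGE * scale * np.eye(cov.shape[0])
        means.append(mu)
        covs.append(cov)
        counts.append(len(coords))
    priors = np.asarray(counts, dtype=float)
    priors /= priors.sum()
    return ClassModel(np.asarray(means), np.asarray(covs), priors)


def _log_gaussian(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = x - mu
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, d.T)
    maha = np.einsum("ij,ij->j", sol, sol)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    k = cov.shape[0]
    return -0.5 * (maha + logdet + k * np.log(2.0 * np.pi))


def classify(image: ScalarVolume, sd_volume: ScalarVolume, model: ClassModel) -> ScalarVolume:
    """MAP label per voxel: +1.0 (object) where the object posterior strictly
    exceeds the gel posterior, else -1.0 (gel).  Ties go to gel — the
    conservative choice for a force that inflates through object territory.
    """
    image.require_same_grid(sd_volume)
    feats = np.stack(
        [image.values.ravel(), sd_volume.values.ravel()], axis=1
    ).astype(float)
    log_post_obj = _log_gaussian(feats, model.means[0], model.covariances[0]) + np.log(
        model.priors[0]
    )
    log_post_gel = _log_gaussian(feats, model.means[1], model.covariances[1]) + np.log(
        model.priors[1]
    )
    labels = np.where(log_post_obj > log_post_gel, OBJECT_VALUE, GEL_VALUE)
    return image.like(labels.reshape(image.shape).astype(np.float32))


def classify_volume(
    image: ScalarVolume, training: TrainingSet, sd_window: int = 5
) -> ScalarVolume:
    """Convenience pipeline: SD features, fit, classify."""
    sd = local_sd_volume(image, sd_window)
    model = fit(image, sd, training)
    return classify(image, sd, model)
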