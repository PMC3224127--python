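"""The multi-mesh, multi-resolution deformation loop.

Pipeline per run: classify the volume (object vs gel), build the tube mask,
seed identical spherical simplex meshes at the user's N points, then deform
all meshes simultaneously through a staged schedule — a low-resolution
inflation stage (strong balloon, high smoothness) followed by several
refined stages (weak balloon, stronger gradient, low smoothness).  Every
few iterations the meshes are rasterized, collision energies rebuilt, and
any mesh found colliding has its ballooning latched off for the rest of the
stage.  Every vertex displacement is clamped to the tube mask.  A mesh
converges when, over the recent iteration window, more than half of its
vertex displacements fall below the displacement threshold; converged
meshes are frozen until the stage ends.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import collision as collision_mod
from . import forces as forces_mod
from .classifier import TrainingSet, classify_volume
from .forces import StageParameters
from .mesh import SimplexMesh, build_simplex_sphere, rasterize, refine
from .tube import clamp_displacements, find_thresholds, make_tube_mask
from .volume import BinaryMask, ScalarVolume

logger = logging.getLogger(__name__)


class SeedError(ValueError):
    """Raised when a seed point cannot initialize a mesh."""


def default_stage_schedule(n_high_res: int = 3) -> list[StageParameters]:
    """The standard two-regime schedule.

    Stage 1 (low resolution): no edge force, strong balloon (0.08) and
    internal (0.9) weights, gradient 0.3, collision 0.4, smoothness 12 —
    rapid, smooth, self-intersection-free expansion.  Each refined stage:
    balloon 0.02, internal 0.7, gradient 0.4, collision 0.3, smoothness 3 —
    boundary recovery with slight touching allowed.
    """
    stage1 = StageParameters(
        w_internal=0.9,
        w_gradient=0.3,
        w_edge=0.0,
        w_balloon=0.08,
        w_collision=0.4,
        smoothness_scale=12,
        max_iterations=200,
    )
    high = [
        StageParameters(
            w_internal=0.7,
            w_gradient=0.4,
            w_edge=0.0,
            w_balloon=0.02,
            w_collision=0.3,
            smoothness_scale=3,
            gradient_search_radius=2,
            max_iterations=100,
        )
        for _ in range(n_high_res)
    ]
    return [stage1] + high


@dataclass
class RunConfig:
    """Everything one deformation run needs besides the image and training."""

    seeds: np.ndarray  # (N, 3) world coordinates
    sphere_radius: float = 5.0  # mm
    initial_subdivisions: int = 1
    stages: list = dc_field(default_factory=default_stage_schedule)
    collision_check_interval: int = 5
    collision_mode: str = "xor"
    collision_enabled: bool = True  # False: no energies, latch or collision force
    displacement_threshold: float = 0.0001  # mm
    activity_threshold: float = 0.5
    activity_window: int = 10
    max_high_res_stages: int = 3
    sd_window: int = 5
    gradient_sigma: float = 1.0  # voxels, smoothing before gradient magnitude
    histogram_bins: int = 256
    tube_cleanup: bool = True
    refine_min_edge_voxels: float = 1.0  # stop refining below image resolution
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.seeds = np.atleast_2d(np.asarray(self.seeds, dtype=float))
        if self.seeds.shape[0] < 1 or self.seeds.shape[1] != 3:
            raise ValueError(f"seeds must be (N, 3) with N >= 1, got {self.seeds.shape}")
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.displacement_threshold <= 0 or self.activity_threshold <= 0:
            raise ValueError("thresholds must be positive")
        n_high = len(self.stages) - 1
        if n_high > self.max_high_res_stages:
            self.stages = self.stages[: 1 + self.max_high_res_stages]


@dataclass
class MeshState:
    """One mesh plus its per-stage control flags and activity history."""

    mesh: SimplexMesh
    converged: bool = False
    balloon_latched: bool = False
    inactive_history: list = dc_field(default_factory=list)

    def reset_for_stage(self) -> None:
        # the balloon latch resets per stage: a mesh halted by an early
        # spurious contact regains its (weaker) inflation in later stages,
        # which is what lets perturbed seed positions recover
        self.converged = False
        self.balloon_latched = False
        self.inactive_history = []

    def record_displacement(self, displacement: np.ndarray, window: int, threshold: float) -> None:
        inactive = np.linalg.norm(displacement, axis=1) < threshold
        self.inactive_history.append(inactive)
        if len(self.inactive_history) > window:
            self.inactive_history.pop(0)

    def activity_ratio(self) -> float:
        """Fraction of inactive vertex-iterations over the recorded window."""
        if not self.inactive_history:
            return 0.0
        return float(np.mean(self.inactive_history))


def initialize(config: RunConfig, tube_mask: BinaryMask) -> list[MeshState]:
    """N identical spheres centered at the seeds.

    Every seed must lie strictly inside the tube mask; seeds closer together
    than one sphere diameter draw a warning (the spheres would start
    overlapping).
    """
    seeds = config.seeds
    if len(np.unique(seeds, axis=0)) != len(seeds):
        raise SeedError("seed points must be pairwise distinct")
    inside = tube_mask.sample_nearest(seeds, outside=0.0)
    for k, ok in enumerate(np.atleast_1d(inside)):
        if ok < 0.5:
            raise SeedError(
                f"seed {k} at {seeds[k].tolist()} lies outside the tube mask"
            )
    dmin = 2.0 * config.sphere_radius
    for a in range(len(seeds)):
        for b in range(a + 1, len(seeds)):
            d = float(np.linalg.norm(seeds[a] - seeds[b]))
            if d < dmin:
                logger.warning(
                    "seeds %d and %d are %.1f mm apart (< 2 x radius %.1f): "
                    "initial spheres overlap",
                    a, b, d, config.sphere_radius,
                )
    return [
        MeshState(
            build_simplex_sphere(s, config.sphere_radius, config.initial_subdivisions)
        )
        for s in seeds
    ]


def check_convergence(state: MeshState, config: RunConfig) -> bool:
    """A mesh is converged when more than `activity_threshold` of its
    vertex displacements over the last `activity_window` iterations fall
    below `displacement_threshold` (strict inequality)."""
    if len(state.inactive_history) < config.activity_window:
        return False
    return state.activity_ratio() > config.activity_threshold


def _gradient_magnitude(image: ScalarVolume, sigma: float) -> ScalarVolume:
    g = ndimage.gaussian_gradient_magnitude(image.values.astype(float), sigma=sigma)
    return image.like(g)


def run(
    image: ScalarVolume,
    config: RunConfig,
    training: TrainingSet,
    out_dir: str | Path | None = None,
    classified: ScalarVolume | None = None,
    dump_collision: bool = False,
) -> list[BinaryMask]:
    """Full segmentation run; returns one binary mask per seed.

    Writes masks (``mask_000.nii`` ...) and a JSON run report when
    `out_dir` is given.  A precomputed `classified` volume may be passed to
    skip classification (it must share the image grid).  The algorithm is
    deterministic: identical inputs give bit-identical masks.
    """
    t_start = time.time()
    report: dict = {"stages": [], "n_meshes": int(len(config.seeds))}

    if classified is None:
        classified = classify_volume(image, training, config.sd_window)
    else:
        image.require_same_grid(classified)

    thresholds = find_thresholds(image, config.histogram_bins)
    tube = make_tube_mask(image, thresholds, cleanup=config.tube_cleanup)
    report["tube_thresholds"] = {
        "t_low": thresholds.t_low,
        "t_high": thresholds.t_high,
    }

    gradmag = _gradient_magnitude(image, config.gradient_sigma)
    # the container wall is the strongest edge in the volume and would
    # capture any vertex within search range; it is excluded territory
    # (tube constraint), so blank the gradient field on and beyond it
    # the container wall dominates both image terms near it: its edge is the
    # strongest gradient in the volume, and the local-SD feature mislabels
    # the adjacent gel band as object.  Territory within the wall margin is
    # governed by the hard tube constraint, not image evidence, so both the
    # gradient field and the balloon's classified map are neutralized there.
    interior = ndimage.binary_erosion(tube.values.astype(bool), iterations=2)
    gradmag.values = np.where(interior, gradmag.values, 0.0)
    balloon_classified = classified.like(
        np.where(interior, classified.values, -1.0).astype(np.float32)
    )
    states = initialize(config, tube)
    interval = int(config.collision_check_interval)

    for stage_idx, params in enumerate(config.stages):
        stage_t0 = time.time()
        if stage_idx > 0:
            # refine only while the mesh is coarser than the image: finer
            # vertices than voxels add no boundary information and chase
            # per-voxel noise
            h = float(np.mean(image.spacing))
            for st in states:
                edges = np.linalg.norm(
                    st.mesh.vertices - st.mesh.vertices[st.mesh.neighbors[:, 0]], axis=1
                )
                if np.median(edges) > config.refine_min_edge_voxels * h:
                    st.mesh = refine(st.mesh)
        for st in states:
            st.reset_for_stage()
        energies = None
        n_iter = 0
        for it in range(params.max_iterations):
            if it % interval == 0 and config.collision_enabled:
                masks = [rasterize(st.mesh, image) for st in states]
                eset = collision_mod.build_energy_images(
                    masks, mode=config.collision_mode, iteration_stamp=it
                )
                energies = eset.energies
                exclusions = [
                    en.like_mask(
                        ndimage.binary_dilation(
                            en.values.astype(bool), iterations=2
                        ).astype(np.uint8)
                    )
                    for en in energies
                ]
            elif energies is None:
                zero = BinaryMask.from_volume_grid(
                    image, np.zeros(image.shape, dtype=np.uint8)
                )
                energies = [zero] * len(states)
                exclusions = [zero] * len(states)
                for st, en in zip(states, energies):
                    colliding = collision_mod.detect_collisions(st.mesh, en)
                    if len(colliding) and not st.balloon_latched:
                        st.balloon_latched = True
                        logger.info(
                            "stage %d it %d: mesh latched (%d colliding vertices)",
                            stage_idx, it, len(colliding),
                        )
            # synchronous update: all forces see positions from the
            # iteration start, so results are independent of mesh order
            updates = []
            for st, en, ex in zip(states, energies, exclusions):
                if st.converged:
                    updates.append(None)
                    continue
                mesh = st.mesh
                f_int = forces_mod.internal_forces(mesh, params)
                f_grad = forces_mod.gradient_forces(
                    gradmag, mesh, params,
                    curvature_comp=config.gradient_sigma**2,
                    foreign=ex,
                )
                f_edge = (
                    forces_mod.edge_forces(image, mesh, params)
                    if params.w_edge > 0
                    else np.zeros_like(mesh.vertices)
                )
                f_ball = forces_mod.balloon_forces(balloon_classified, mesh, params)
                f_coll = forces_mod.collision_forces(en, gradmag, mesh, params)
                ext = forces_mod.external_forces_sum(
                    params, f_grad, f_edge, f_ball, f_coll,
                    balloon_weight=0.0 if st.balloon_latched else None,
                )
                updates.append(params.w_internal * f_int + ext)
            for st, total in zip(states, updates):
                if total is None:
                    continue
                old = st.mesh.vertices.copy()
                h = float(np.mean(image.spacing))
                forces_mod.step(st.mesh, total, params, max_step=params.max_displacement * h)
                st.mesh.vertices = clamp_displacements(old, st.mesh.vertices, tube)
                st.record_displacement(
                    st.mesh.vertices - old,
                    config.activity_window,
                    config.displacement_threshold,
                )
                if check_convergence(st, config):
                    st.converged = True
            n_iter = it + 1
            if all(st.converged for st in states):
                break
        if not all(st.converged for st in states):
            logger.warning(
                "stage %d hit the iteration cap (%d) before all meshes converged",
                stage_idx, params.max_iterations,
            )
        report["stages"].append(
            {
                "stage": stage_idx,
                "iterations": n_iter,
                "n_vertices": int(states[0].mesh.n_vertices),
                "weights": {
                    "w_internal": params.w_internal,
                    "w_gradient": params.w_gradient,
                    "w_edge": params.w_edge,
                    "w_balloon": params.w_balloon,
                    "w_collision": params.w_collision,
                },
                "smoothness_scale": params.smoothness_scale,
                "activity_ratios": [st.activity_ratio() for st in states],
                "converged": [bool(st.converged) for st in states],
                "balloon_latched": [bool(st.balloon_latched) for st in states],
                "seconds": time.time() - stage_t0,
            }
        )

    final_masks = [rasterize(st.mesh, image) for st in states]
    report["seconds_total"] = time.time() - t_start

    if out_dir is not None:
        from . import io as io_mod

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for k, m in enumerate(final_masks):
            io_mod.write_volume(m, out / f"mask_{k:03d}.nii", dtype=np.uint8)
        if dump_collision:
            eset = collision_mod.build_energy_images(
                final_masks, mode=config.collision_mode
            )
            for k, en in enumerate(eset.energies):
                io_mod.write_volume(en, out / f"collision_{k:03d}.nii", dtype=np.uint8)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    run.last_report = report  # stashed for callers that want diagnostics
    run.last_states = states
    return final_masks


run.last_report = None
run.last_states = None
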