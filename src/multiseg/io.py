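"""File formats: NIfTI volumes and masks, whitespace seed lists, CSV
training sets, YAML run configuration, JSON run reports, and mesh export
(legacy-ASCII VTK polydata or OBJ, with a JSON sidecar carrying the
simplex connectivity).

NIfTI is the primary volume dialect; other formats readable by SimpleITK
(e.g. MINC) are accepted read-only when that reader is available.  The
world convention throughout the package is origin + spacing * index with
no rotation, so only the affine's scale and translation are used.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .classifier import TrainingSet
from .engine import RunConfig
from .forces import StageParameters
from .mesh import SimplexMesh
from .volume import BinaryMask, ScalarVolume


class FileFormatError(ValueError):
    """Raised for malformed or unsupported input files."""


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a 3-D scalar volume (NIfTI via nibabel; else SimpleITK)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
        spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        origin = affine[:3, 3]
        return ScalarVolume(np.asarray(data, dtype=data.dtype), spacing, origin)
    try:
        import SimpleITK as sitk
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise FileFormatError(
            f"unsupported volume format {path.suffix!r} (SimpleITK unavailable)"
        ) from exc
    img = sitk.ReadImage(str(path))
    # SimpleITK indexes (z, y, x); transpose to our (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ScalarVolume(
        data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin())
    )


def write_volume(volume: ScalarVolume, path: str | Path, dtype=np.float32) -> None:
    """Write a volume as NIfTI; masks should pass ``dtype=np.uint8``."""
    import nibabel as nib

    path = Path(path)
    if not _is_nifti(path):
        raise FileFormatError(f"write_volume only writes NIfTI, got {path.name!r}")
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=dtype), affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    v = read_volume(path)
    return BinaryMask((np.asarray(v.values) > 0.5).astype(np.uint8), v.spacing, v.origin)


# ---------------------------------------------------------------------------
# Seeds and training sets
# ---------------------------------------------------------------------------


def read_seeds(path: str | Path) -> np.ndarray:
    """Whitespace-separated ``x y z`` world coordinates, one seed per line.

    Blank lines and ``#`` comments are skipped.
    """
    seeds = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 3:
                raise FileFormatError(
                    f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}: {line!r}"
                )
            try:
                seeds.append([float(p) for p in parts])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
    if not seeds:
        raise FileFormatError(f"{path}: no seed points found")
    return np.asarray(seeds)


def write_seeds(seeds: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in np.atleast_2d(seeds):
            fh.write(f"{s[0]:.6g} {s[1]:.6g} {s[2]:.6g}\n")


_LABEL_ALIASES = {"object": "object", "embryo": "object", "gel": "gel"}


def read_training(path: str | Path) -> TrainingSet:
    """CSV ``x,y,z,label`` with 0-based voxel coordinates; labels are
    ``object`` (alias ``embryo``) or ``gel``.  A header row is optional."""
    obj, gel = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            text = line.strip()
            if not text:
                continue
            parts = [p.strip() for p in text.split(",")]
            if lineno == 1 and parts[-1].lower() == "label":
                continue
            if len(parts) != 4:
                raise FileFormatError(
                    f"{path}:{lineno}: expected 'x,y,z,label', got {line!r}"
                )
            label = _LABEL_ALIASES.get(parts[3].lower())
            if label is None:
                raise FileFormatError(
                    f"{path}:{lineno}: unknown class label {parts[3]!r}"
                )
            try:
                coord = [int(p) for p in parts[:3]]
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
            (obj if label == "object" else gel).append(coord)
    return TrainingSet(np.asarray(obj), np.asarray(gel))


def write_training(training: TrainingSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x,y,z,label\n")
        for c in training.object_coords:
            fh.write(f"{c[0]},{c[1]},{c[2]},object\n")
        for c in training.gel_coords:
            fh.write(f"{c[0]},{c[1]},{c[2]},gel\n")


# ---------------------------------------------------------------------------
# Run configuration (YAML) and reports (JSON)
# ---------------------------------------------------------------------------


def read_config(path: str | Path, seeds: np.ndarray) -> RunConfig:
    """YAML file mirroring RunConfig (minus seeds, which come from the seed
    file); the ``stages`` entry is a list of StageParameters mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FileFormatError(f"{path}: expected a mapping at top level")
    stages_raw = raw.pop("stages", None)
    kwargs = dict(raw)
    if stages_raw is not None:
        kwargs["stages"] = [StageParameters(**s) for s in stages_raw]
    try:
        return RunConfig(seeds=seeds, **kwargs)
    except TypeError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_config(config: RunConfig, path: str | Path) -> None:
    data = asdict(config)
    data.pop("seeds")
    data["stages"] = [asdict(s) for s in config.stages]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# Meshes: surface file + JSON sidecar with the simplex connectivity
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".simplex.json")


def _write_sidecar(mesh: SimplexMesh, path: Path) -> None:
    payload = {
        "n_vertices": int(mesh.n_vertices),
        "neighbors": mesh.neighbors.tolist(),
        "tri_faces": mesh.tri_faces.tolist(),
        "rings": [r.tolist() for r in mesh.rings],
        "reference_eps": mesh.reference_eps.tolist(),
        "reference_angle": mesh.reference_angle.tolist(),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(payload, fh)


def _rebuild_from_sidecar(vertices: np.ndarray, path: Path) -> SimplexMesh:
    with open(_sidecar_path(path)) as fh:
        payload = json.load(fh)
    return SimplexMesh(
        vertices,
        np.asarray(payload["neighbors"], dtype=np.int64),
        np.asarray(payload["tri_faces"], dtype=np.int64),
        [np.asarray(r, dtype=np.int64) for r in payload["rings"]],
        reference_eps=np.asarray(payload["reference_eps"]),
        reference_angle=np.asarray(payload["reference_angle"]),
    )


def write_mesh(mesh: SimplexMesh, path: str | Path) -> None:
    """Write the fan-triangulated surface (.vtk legacy ASCII or .obj) plus a
    ``*.simplex.json`` sidecar with the simplex connectivity and reference
    parameters, allowing exact reconstruction."""
    path = Path(path)
    pts, faces = mesh.surface_points_faces()
    if path.suffix.lower() == ".vtk":
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write("simplex mesh fan surface\nASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {len(pts)} float\n")
            for p in pts:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    elif path.suffix.lower() == ".obj":
        import trimesh

        trimesh.Trimesh(vertices=pts, faces=faces, process=False).export(str(path))
    else:
        raise FileFormatError(f"unsupported mesh format {path.suffix!r}")
    _write_sidecar(mesh, path)


def read_mesh(path: str | Path) -> SimplexMesh:
    """Read a mesh written by :func:`write_mesh` (sidecar required)."""
    path = Path(path)
    if not _sidecar_path(path).exists():
        raise FileFormatError(f"missing simplex sidecar for {path}")
    if path.suffix.lower() == ".vtk":
        pts = _read_vtk_points(path)
    elif path.suffix.lower() == ".obj":
        import trimesh

        pts = np.asarray(trimesh.load(str(path), process=False).vertices)
    else:
        raise FileFormatError(f"unsupported mesh format {path.suffix!r}")
    with open(_sidecar_path(path)) as fh:
        n = json.load(fh)["n_vertices"]
    vertices = pts[len(pts) - n :]
    return _rebuild_from_sidecar(vertices, path)


def _read_vtk_points(path: Path) -> np.ndarray:
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("POINTS"):
            count = int(line.split()[1])
            vals: list[float] = []
            j = i + 1
            while len(vals) < 3 * count:
                vals.extend(float(x) for x in lines[j].split())
                j += 1
            return np.asarray(vals).reshape(count, 3)
    raise FileFormatError(f"{path}: no POINTS section found")
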