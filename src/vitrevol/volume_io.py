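"""Reading and writing of volumes, masks, meshes and metric tables.

Volumes travel as NIfTI-1 (spacing in the header zooms) or multi-page TIFF
with a JSON sidecar carrying the per-axis spacing, since baseline TIFF has
no 3D calibration. Refusing to guess: a volume without recoverable spacing
is an error, never a silent default.

On disk the page axis of a TIFF and the last axis of the in-memory grid are
exchanged so that each stored page is one en-face frame.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import trimesh

from .types import CavityMetrics, CavityModel, OCTVolume, StructureMetric

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "extract_meshes",
    "export_mesh",
    "write_metrics",
    "read_metrics",
    "write_config",
    "read_config",
]

_SIDE_SUFFIX = ".spacing.json"


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + _SIDE_SUFFIX)


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    raise ValueError(f"cannot infer volume format from {path.name!r}; pass format=")


def write_volume(
    volume: OCTVolume, path, fmt: Optional[str] = None, dtype=np.float32
) -> Path:
    """Write an OCT volume (or any calibrated scalar grid) to disk."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    data = np.asarray(volume.intensities, dtype=dtype)
    if fmt == "nifti":
        affine = np.diag(list(volume.spacing) + [1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(path))
    elif fmt == "tiff":
        # pages along the depth axis: store (z, x, y)
        tifffile.imwrite(str(path), np.moveaxis(data, 2, 0))
        meta = {
            "spacing_mm": list(volume.spacing),
            "laterality": volume.laterality,
            "fovea_xy_mm": list(volume.fovea_xy) if volume.fovea_xy else None,
            "disc_xy_mm": list(volume.disc_xy) if volume.disc_xy else None,
        }
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unsupported volume format {fmt!r}")
    return path


def read_volume(path, fmt: Optional[str] = None, normalize: bool = True) -> OCTVolume:
    """Read a volume, recovering spacing from the NIfTI header or sidecar.

    Intensities are min-max scaled to [0, 1] unless ``normalize=False``
    (label volumes are read through :func:`read_mask` instead).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    laterality, fovea, disc = "right", None, None
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj).astype(np.float32)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {data.ndim}D data in {path.name}")
        zooms = img.header.get_zooms()[:3]
        if any(not np.isfinite(z) or z <= 0 for z in zooms):
            raise ValueError(f"{path.name}: NIfTI header carries no positive voxel spacing")
        spacing = tuple(float(z) for z in zooms)
    elif fmt == "tiff":
        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {data.ndim}D data in {path.name}")
        data = np.moveaxis(data, 0, 2).astype(np.float32)
        side = _sidecar(path)
        if not side.exists():
            raise ValueError(
                f"{path.name}: spacing sidecar {side.name} is missing; TIFF volumes "
                "require explicit physical spacing"
            )
        meta = json.loads(side.read_text())
        spacing = tuple(float(s) for s in meta["spacing_mm"])
        laterality = meta.get("laterality", "right")
        fovea = tuple(meta["fovea_xy_mm"]) if meta.get("fovea_xy_mm") else None
        disc = tuple(meta["disc_xy_mm"]) if meta.get("disc_xy_mm") else None
    else:
        raise ValueError(f"unsupported volume format {fmt!r}")

    if normalize:
        lo, hi = float(data.min()), float(data.max())
        data = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    return OCTVolume(
        intensities=data,
        spacing=spacing,
        laterality=laterality,
        fovea_xy=fovea,
        disc_xy=disc,
    )


def write_mask(mask: np.ndarray, spacing, path, fmt: Optional[str] = None) -> Path:
    """Write a binary or label grid as an 8-bit volume."""
    grid = np.asarray(mask)
    if grid.max(initial=0) > 255:
        raise ValueError("label grid exceeds 8-bit range")
    vol = OCTVolume(intensities=grid.astype(np.uint8), spacing=spacing)
    return write_volume(vol, path, fmt=fmt, dtype=np.uint8)


def read_mask(path, fmt: Optional[str] = None) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    vol = read_volume(path, fmt=fmt, normalize=False)
    return vol.intensities.astype(np.uint8), vol.spacing


# --------------------------------------------------------------------------
# meshes


def extract_meshes(model: CavityModel) -> Dict[int, trimesh.Trimesh]:
    """Marching-cubes triangulation of every labeled cavity, in mm.

    Uses the same iso-level-0.5 triangulation as the surface-area
    measurement, so exported areas agree with the reported biometry.
    """
    from skimage import measure

    e = model.voxel_edge
    meshes: Dict[int, trimesh.Trimesh] = {}
    for lab in model.labels:
        mask = np.pad(model.label_grid == lab, 1).astype(np.float32)
        verts, faces, _, _ = measure.marching_cubes(mask, level=0.5, spacing=(e, e, e))
        verts = verts - e  # undo the 1-voxel zero pad
        meshes[lab] = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return meshes


def export_mesh(model: CavityModel, path, fmt: Optional[str] = None) -> List[Path]:
    """Export the cavity model as STL (one file per structure) or PLY.

    PLY keeps all cavities in a single ascii file; STL, which has no label
    channel, writes ``<stem>_<class><k>.stl`` per cavity.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "ply"
    if fmt not in ("stl", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r}")
    meshes = extract_meshes(model)
    if not meshes:
        raise ValueError("cavity model is empty; nothing to export")
    written: List[Path] = []
    if fmt == "ply":
        combined = trimesh.util.concatenate(list(meshes.values()))
        combined.export(str(path), file_type="ply", encoding="ascii")
        written.append(path)
    else:
        for lab, mesh in meshes.items():
            cls = model.class_map.get(lab, "other")
            out = path.with_name(f"{path.stem}_{cls}{lab}.stl")
            mesh.export(str(out), file_type="stl")
            written.append(out)
    return written


# --------------------------------------------------------------------------
# metric tables

_STRUCTURES = ("whole", "PMP", "CC", "other")
_FIELDS = ("volume_mm3", "volume_err_mm3", "area_mm2", "area_err_mm2")


def metrics_to_row(metrics: CavityMetrics) -> Dict[str, object]:
    row: Dict[str, object] = {"eye_id": metrics.eye_id}
    for s in _STRUCTURES:
        m = metrics.structures.get(s)
        for f in _FIELDS:
            row[f"{s}_{f}"] = getattr(m, f) if m is not None else np.nan
    row["connected_pmp_cc"] = metrics.connected_pmp_cc
    return row


def write_metrics(metrics_list, path) -> Path:
    """Write one CSV row per eye: volume/area (+/- error) per structure."""
    if isinstance(metrics_list, CavityMetrics):
        metrics_list = [metrics_list]
    if not metrics_list:
        raise ValueError("no metrics to write")
    df = pd.DataFrame([metrics_to_row(m) for m in metrics_list])
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_metrics(path) -> List[CavityMetrics]:
    df = pd.read_csv(path)
    out: List[CavityMetrics] = []
    for _, row in df.iterrows():
        structures: Dict[str, StructureMetric] = {}
        for s in _STRUCTURES:
            vals = [row.get(f"{s}_{f}", np.nan) for f in _FIELDS]
            if all(pd.notna(v) for v in vals):
                structures[s] = StructureMetric(*[float(v) for v in vals])
        conn = row.get("connected_pmp_cc")
        out.append(
            CavityMetrics(
                structures=structures,
                connected_pmp_cc=None if pd.isna(conn) else bool(conn),
                eye_id=str(row.get("eye_id", "")),
            )
        )
    return out


# --------------------------------------------------------------------------
# plain-text key=value configuration


def write_config(config: Dict[str, object], path) -> Path:
    lines = [f"{k} = {_fmt_value(v)}" for k, v in config.items()]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def _fmt_value(v) -> str:
    if isinstance(v, (list, tuple)):
        return ",".join(str(x) for x in v)
    return str(v)


def read_config(path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out
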