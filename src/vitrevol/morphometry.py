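"""Calibrated volumetry and surface-area biometry of fluid cavities.

The cleaned fused mask is resampled onto an isotropic lattice whose voxel
edge defaults to 12/256 mm = 0.046875 mm; the per-voxel cube is then
0.046875**3 ~= 1.03e-4 mm^3, the calibration used for all printed volumes.
Volume is voxel counting times the cube volume; surface area is the summed
triangle area of the marching-cubes isosurface of the binary indicator at
level 0.5 (vertices linearly interpolated on the voxel-center lattice, no
pre-smoothing).

Anatomical attribution: the connected component whose en-face projection
covers the fovea is the premacular pocket (PMP), the one covering the optic
disc is Cloquet's canal (CC). When a single component covers both — the
common situation, since most eyes show a PMP-CC connection — it is split by
within-component geodesic distance to the two landmark columns and flagged
as connected.

Propagated segmentation error: the volume uncertainty assumes half-a-voxel
boundary uncertainty across the entire surface, dV = A * edge / 2; the area
uncertainty is half the spread between the areas after one-voxel dilation
and erosion, dA = (A+ - A-) / 2.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.graph import MCP

from .types import CavityMetrics, CavityModel, StructureMetric

__all__ = [
    "DEFAULT_VOXEL_EDGE",
    "rescale_isotropic",
    "label_components",
    "classify_cavities",
    "cavity_volume",
    "cavity_surface_area",
    "propagate_error",
    "detect_connection",
    "compute_metrics",
]

#: 12 mm en-face field / 256 A-scans; its cube is the printed 1.03e-4 mm^3.
DEFAULT_VOXEL_EDGE = 12.0 / 256.0


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)


# --------------------------------------------------------------------------
# resampling and labeling


def rescale_isotropic(
    mask: np.ndarray,
    spacing: Tuple[float, float, float],
    voxel_edge: float = DEFAULT_VOXEL_EDGE,
) -> np.ndarray:
    """Nearest-neighbor resampling onto an isotropic voxel lattice.

    The target grid covers the same physical field; each target voxel takes
    the value of the source voxel containing its center. Total fluid volume
    is preserved to within the boundary-voxel quantization (<2% for
    cavity-scale structures at the default edge).
    """
    if voxel_edge <= 0:
        raise ValueError("voxel edge must be positive")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive values, got {spacing}")
    grid = np.asarray(mask).astype(bool)
    extent = [n * s for n, s in zip(grid.shape, spacing)]
    target_shape = tuple(max(1, int(round(e / voxel_edge))) for e in extent)
    idx = []
    for axis in range(3):
        centers = (np.arange(target_shape[axis]) + 0.5) * voxel_edge
        src = np.floor(centers / spacing[axis]).astype(np.intp)
        idx.append(np.clip(src, 0, grid.shape[axis] - 1))
    return grid[np.ix_(idx[0], idx[1], idx[2])]


def label_components(
    grid: np.ndarray,
    connectivity: int = 6,
    voxel_edge: float = DEFAULT_VOXEL_EDGE,
) -> CavityModel:
    """Connected-component labeling with a deterministic label order.

    Labels are assigned in descending component size; ties are broken by
    the lexicographically first voxel of each component.
    """
    mask = np.asarray(grid).astype(bool)
    raw, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return CavityModel(
            label_grid=np.zeros(mask.shape, dtype=np.int32),
            voxel_edge=voxel_edge,
            connectivity=connectivity,
        )
    sizes = np.bincount(raw.ravel())[1:]
    flat_first = np.full(n + 1, raw.size, dtype=np.int64)
    flat = raw.ravel()
    nz = np.flatnonzero(flat)
    # first (lexicographically smallest) flat index per raw label
    np.minimum.at(flat_first, flat[nz], nz)
    order = sorted(range(1, n + 1), key=lambda k: (-int(sizes[k - 1]), int(flat_first[k])))
    remap = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return CavityModel(
        label_grid=remap[raw],
        voxel_edge=voxel_edge,
        connectivity=connectivity,
    )


# --------------------------------------------------------------------------
# anatomical classification


def _landmark_column(model: CavityModel, xy_mm: Tuple[float, float]) -> Tuple[int, int]:
    shape = model.label_grid.shape
    ix = int(np.floor(xy_mm[0] / model.voxel_edge))
    iy = int(np.floor(xy_mm[1] / model.voxel_edge))
    if not (0 <= ix < shape[0] and 0 <= iy < shape[1]):
        raise ValueError(f"landmark {xy_mm} mm lies outside the en-face field")
    return ix, iy


def _component_at_column(
    model: CavityModel, col: Tuple[int, int], search_radius_mm: float = 0.5
) -> Optional[int]:
    """Label whose en-face projection covers the column, else the nearest
    component within ``search_radius_mm`` en-face."""
    ix, iy = col
    column = model.label_grid[ix, iy, :]
    hit = column[column > 0]
    if hit.size:
        return int(hit[0])
    r = max(1, int(round(search_radius_mm / model.voxel_edge)))
    x0, x1 = max(0, ix - r), min(model.label_grid.shape[0], ix + r + 1)
    y0, y1 = max(0, iy - r), min(model.label_grid.shape[1], iy + r + 1)
    patch = model.label_grid[x0:x1, y0:y1, :]
    cand = patch[patch > 0]
    if not cand.size:
        return None
    xs, ys, _ = np.nonzero(patch)
    d2 = (xs + x0 - ix) ** 2 + (ys + y0 - iy) ** 2
    return int(cand[np.argmin(d2)])


_OFFSETS_6 = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]


def _geodesic_split(
    comp: np.ndarray, seeds_a: np.ndarray, seeds_b: np.ndarray
) -> np.ndarray:
    """Partition a connected mask by geodesic (6-connected) distance to two
    seed sets; returns int grid with 1 = nearer A (ties to A), 2 = nearer B."""
    costs = np.where(comp, 1.0, np.inf)
    dist_a = MCP(costs, offsets=_OFFSETS_6).find_costs(np.argwhere(seeds_a))[0]
    dist_b = MCP(costs, offsets=_OFFSETS_6).find_costs(np.argwhere(seeds_b))[0]
    out = np.zeros(comp.shape, dtype=np.int8)
    out[comp] = np.where(dist_a[comp] <= dist_b[comp], 1, 2)
    return out


def classify_cavities(
    model: CavityModel,
    fovea_xy: Optional[Tuple[float, float]] = None,
    disc_xy: Optional[Tuple[float, float]] = None,
    laterality: Optional[str] = None,
) -> CavityModel:
    """Assign anatomical classes (PMP / CC / other) to labeled cavities.

    A component covering the foveal column becomes the PMP; the one covering
    the disc column becomes the CC; a single component covering both is split
    by two-source geodesic distance into a PMP part and a CC part and flagged
    ``connected_pmp_cc``. Remaining components are classed ``other``.
    """
    fovea_xy = fovea_xy if fovea_xy is not None else model.fovea_xy
    disc_xy = disc_xy if disc_xy is not None else model.disc_xy
    if fovea_xy is None or disc_xy is None:
        raise ValueError("fovea and disc landmarks are required for classification")
    grid = model.label_grid
    fcol = _landmark_column(model, fovea_xy)
    dcol = _landmark_column(model, disc_xy)
    pmp_label = _component_at_column(model, fcol)
    cc_label = _component_at_column(model, dcol)

    class_map: Dict[int, str] = {lab: "other" for lab in model.labels}
    connected: Optional[bool] = None
    out_grid = grid.astype(np.int32, copy=True)

    if pmp_label is not None and pmp_label == cc_label:
        # merged component: split by geodesic distance to the landmark columns
        comp = grid == pmp_label
        seeds_a = np.zeros_like(comp)
        seeds_a[fcol[0], fcol[1], :] = True
        seeds_a &= comp
        seeds_b = np.zeros_like(comp)
        seeds_b[dcol[0], dcol[1], :] = True
        seeds_b &= comp
        if not seeds_a.any() or not seeds_b.any():
            # landmark matched by proximity search, not exact cover: seed from
            # the nearest component voxels en-face
            seeds_a = _nearest_column_seeds(comp, fcol)
            seeds_b = _nearest_column_seeds(comp, dcol)
        part = _geodesic_split(comp, seeds_a, seeds_b)
        new_cc = int(out_grid.max()) + 1
        out_grid[part == 2] = new_cc
        class_map[pmp_label] = "PMP"
        class_map[new_cc] = "CC"
        connected = True
    else:
        if pmp_label is not None:
            class_map[pmp_label] = "PMP"
        if cc_label is not None:
            class_map[cc_label] = "CC"
        connected = (
            False if (pmp_label is not None and cc_label is not None) else None
        )

    return CavityModel(
        label_grid=out_grid,
        voxel_edge=model.voxel_edge,
        class_map=class_map,
        connectivity=model.connectivity,
        connected_pmp_cc=connected,
        fovea_xy=fovea_xy,
        disc_xy=disc_xy,
    )


def _nearest_column_seeds(comp: np.ndarray, col: Tuple[int, int]) -> np.ndarray:
    xs, ys, zs = np.nonzero(comp)
    d2 = (xs - col[0]) ** 2 + (ys - col[1]) ** 2
    best = d2 == d2.min()
    seeds = np.zeros_like(comp)
    seeds[xs[best], ys[best], zs[best]] = True
    return seeds


# --------------------------------------------------------------------------
# biometry


def cavity_volume(model: CavityModel, structure: str = "whole") -> float:
    """Volume in mm^3: foreground voxel count times the voxel cube volume."""
    mask = model.structure_mask(structure)
    return float(mask.sum()) * model.voxel_volume


def _marching_cubes_area(mask: np.ndarray, edge: float) -> float:
    if not mask.any():
        return 0.0
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=(edge, edge, edge)
    )
    return float(measure.mesh_surface_area(verts, faces))


def cavity_surface_area(model: CavityModel, structure: str = "whole") -> float:
    """Surface area in mm^2 of the marching-cubes isosurface at level 0.5.

    The binary indicator is triangulated directly (no smoothing); the known
    small overestimation of binary marching cubes is characterized by the
    digitized-sphere oracle in the test suite.
    """
    mask = model.structure_mask(structure)
    if not mask.any():
        raise ValueError(f"structure {structure!r} is empty; no surface to measure")
    return _marching_cubes_area(mask, model.voxel_edge)


def propagate_error(
    model: CavityModel, structure: str = "whole"
) -> Tuple[float, float, bool]:
    """Propagated segmentation uncertainty (dV mm^3, dA mm^2, eroded_empty).

    dV spreads half a voxel of boundary uncertainty over the whole surface:
    ``dV = A * edge / 2``. dA is half the area spread under one-voxel
    dilation/erosion; a structure that erodes to nothing uses A- = 0 and
    raises the ``eroded_empty`` flag.
    """
    mask = model.structure_mask(structure)
    if not mask.any():
        raise ValueError(f"structure {structure!r} is empty; no error to propagate")
    e = model.voxel_edge
    area = _marching_cubes_area(mask, e)
    struct = _structure(model.connectivity)
    grown = ndimage.binary_dilation(mask, structure=struct)
    shrunk = ndimage.binary_erosion(mask, structure=struct)
    area_plus = _marching_cubes_area(grown, e)
    eroded_empty = not shrunk.any()
    area_minus = 0.0 if eroded_empty else _marching_cubes_area(shrunk, e)
    dv = area * e / 2.0
    da = (area_plus - area_minus) / 2.0
    return dv, da, eroded_empty


def detect_connection(
    model: CavityModel,
    fovea_xy: Optional[Tuple[float, float]] = None,
    disc_xy: Optional[Tuple[float, float]] = None,
) -> Optional[bool]:
    """True iff the PMP and CC voxels share one 6-connected fluid component.

    Operates on the pre-split connectivity: PMP- and CC-classed voxels are
    pooled and relabeled, so a merged component split during classification
    still reports as connected. Returns None (indeterminate) when either
    structure is absent.
    """
    try:
        pmp = model.structure_mask("PMP")
        cc = model.structure_mask("CC")
    except KeyError:
        return None
    if not pmp.any() or not cc.any():
        return None
    merged, _ = ndimage.label(pmp | cc, structure=_structure(6))
    pmp_ids = np.unique(merged[pmp])
    cc_ids = np.unique(merged[cc])
    return bool(np.intersect1d(pmp_ids, cc_ids).size > 0)


def compute_metrics(model: CavityModel, eye_id: str = "") -> CavityMetrics:
    """Full biometry of one classified cavity model.

    Reports volume and surface area with propagated errors for the whole
    cavity set, the PMP, the CC and (when present) the pooled accessory
    cavities, plus the PMP-CC connection flag.
    """
    structures: Dict[str, StructureMetric] = {}
    present = set(model.class_map.values())
    names = ["whole"] + [s for s in ("PMP", "CC", "other") if s in present]
    for name in names:
        mask = model.structure_mask(name)
        if not mask.any():
            continue
        vol = float(mask.sum()) * model.voxel_volume
        area = _marching_cubes_area(mask, model.voxel_edge)
        dv, da, eroded = propagate_error(model, name)
        structures[name] = StructureMetric(
            volume_mm3=vol,
            volume_err_mm3=dv,
            area_mm2=area,
            area_err_mm2=da,
            eroded_to_empty=eroded,
        )
    connected = model.connected_pmp_cc
    if connected is None:
        connected = detect_connection(model)
    return CavityMetrics(structures=structures, connected_pmp_cc=connected, eye_id=eye_id)
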