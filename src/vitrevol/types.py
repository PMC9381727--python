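"""Shared domain containers for the vitreous-cavity pipeline.

Axis convention (fixed throughout the package):

* axis 0 — en-face horizontal ``x`` (nasal–temporal), 12 mm field by default
* axis 1 — en-face vertical ``y`` (superior–inferior), 9 mm field
* axis 2 — depth ``z`` (anterior → posterior), 2.6 mm; the retinal band sits
  at the posterior (high-``z``) extreme

Physical coordinates are voxel-center positions: voxel ``i`` on an axis with
spacing ``s`` is centered at ``(i + 0.5) * s`` mm.

The three orthogonal B-scan planes slice the volume along one axis each:

* ``axial``    — frames indexed along axis 1, each frame an (x, z) image
* ``sagittal`` — frames indexed along axis 0, each frame a (y, z) image
* ``coronal``  — en-face frames indexed along axis 2, each frame an (x, y) image
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

#: Maps plane name -> volume axis along which that plane's frames are stacked.
PLANE_AXIS: Dict[str, int] = {"axial": 1, "sagittal": 0, "coronal": 2}

PLANES = tuple(PLANE_AXIS)


def check_plane(plane: str) -> int:
    """Return the stacking axis for *plane*, rejecting unknown names."""
    try:
        return PLANE_AXIS[plane]
    except KeyError:
        raise ValueError(
            f"unknown plane {plane!r}; expected one of {sorted(PLANE_AXIS)}"
        ) from None


@dataclass
class OCTVolume:
    """A 3D grayscale OCT intensity grid with physical calibration.

    Parameters
    ----------
    intensities
        Scalar grid in ``[0, 1]``, shape ``(nx, ny, nz)``.
    spacing
        Per-axis voxel edge length in mm, strictly positive.
    laterality
        ``"right"`` or ``"left"`` eye.
    fovea_xy, disc_xy
        En-face landmark coordinates in mm (foveal center, optic-disc
        center), used downstream to attribute cavities to anatomy.
    """

    intensities: np.ndarray
    spacing: Tuple[float, float, float]
    laterality: str = "right"
    fovea_xy: Optional[Tuple[float, float]] = None
    disc_xy: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"OCT volume must be 3D, got {self.intensities.ndim}D data"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.laterality not in ("right", "left"):
            raise ValueError(f"laterality must be 'right' or 'left', got {self.laterality!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def field_extent(self) -> Tuple[float, float, float]:
        """Physical size of the scanned field per axis, in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def n_frames(self, plane: str) -> int:
        return self.shape[check_plane(plane)]


@dataclass
class SparseLabelSet:
    """Sparse manual annotations on selected frames of one plane.

    ``labeled_frames`` maps frame index -> strictly binary 2D mask of that
    frame's in-plane shape. ``rater_id`` records who produced the labels.
    """

    plane: str
    labeled_frames: Dict[int, np.ndarray]
    rater_id: str = "rater"

    def __post_init__(self) -> None:
        check_plane(self.plane)
        clean: Dict[int, np.ndarray] = {}
        for idx, mask in self.labeled_frames.items():
            arr = np.asarray(mask)
            if arr.ndim != 2:
                raise ValueError(f"frame {idx}: label mask must be 2D")
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"frame {idx}: label mask must be binary")
            clean[int(idx)] = arr.astype(bool)
        self.labeled_frames = clean

    def validate_against(self, volume: OCTVolume) -> None:
        axis = check_plane(self.plane)
        n = volume.shape[axis]
        frame_shape = tuple(s for a, s in enumerate(volume.shape) if a != axis)
        for idx, mask in self.labeled_frames.items():
            if not 0 <= idx < n:
                raise ValueError(
                    f"labeled frame index {idx} outside plane extent [0, {n})"
                )
            if mask.shape != frame_shape:
                raise ValueError(
                    f"frame {idx}: mask shape {mask.shape} != frame shape {frame_shape}"
                )


@dataclass
class PlaneMask:
    """Binary 3D mask covering every frame of one plane."""

    plane: str
    mask: np.ndarray
    provenance: str = "trained"  # "trained" | "fallback"

    def __post_init__(self) -> None:
        check_plane(self.plane)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("plane mask must be a 3D grid")


@dataclass
class FusedMask:
    """Majority-vote fusion of three per-plane masks.

    ``votes`` keeps the per-voxel count of planes voting positive (0–3);
    ``mask`` is True exactly where ``votes >= 2``.
    """

    mask: np.ndarray
    votes: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.votes = np.asarray(self.votes)
        if self.mask.shape != self.votes.shape:
            raise ValueError("mask and vote grids must share a shape")


@dataclass
class StructureMetric:
    """Volume/area measurement with propagated segmentation error."""

    volume_mm3: float
    volume_err_mm3: float
    area_mm2: float
    area_err_mm2: float
    eroded_to_empty: bool = False


@dataclass
class CavityMetrics:
    """Per-structure and whole-cavity biometry of one eye."""

    structures: Dict[str, StructureMetric]
    connected_pmp_cc: Optional[bool] = None
    eye_id: str = ""

    def get(self, name: str) -> StructureMetric:
        return self.structures[name]


@dataclass
class CavityModel:
    """Component-labeled cavity grid on an isotropic lattice.

    ``label_grid`` holds 0 for background and k >= 1 per cavity;
    ``class_map`` assigns each label an anatomical class (``"PMP"``,
    ``"CC"`` or ``"other"``). ``voxel_volume`` is always ``voxel_edge**3``.
    """

    label_grid: np.ndarray
    voxel_edge: float
    class_map: Dict[int, str] = field(default_factory=dict)
    connectivity: int = 6
    connected_pmp_cc: Optional[bool] = None
    fovea_xy: Optional[Tuple[float, float]] = None
    disc_xy: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid)
        if self.label_grid.ndim != 3:
            raise ValueError("label grid must be 3D")
        if self.voxel_edge <= 0:
            raise ValueError("voxel edge must be positive")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_edge) ** 3

    @property
    def labels(self) -> Tuple[int, ...]:
        return tuple(int(v) for v in np.unique(self.label_grid) if v != 0)

    def structure_mask(self, structure: str) -> np.ndarray:
        """Union of components classed as *structure* (or label id match)."""
        out = np.zeros(self.label_grid.shape, dtype=bool)
        found = False
        for lab, cls in self.class_map.items():
            if cls == structure:
                out |= self.label_grid == lab
                found = True
        if structure == "whole":
            return self.label_grid > 0
        if not found:
            raise KeyError(f"structure {structure!r} not present in class map")
        return out
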