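"""Synthetic posterior-segment OCT phantoms with analytic ground truth.

The generator emulates a 12 x 9 x 2.6 mm swept-source OCT volume of the
posterior vitreous: a bright retinal band at the posterior extreme, vitreous
gel with multiplicative speckle, and dark fluid cavities —

* the premacular vitreous pocket (PMP), a half-ellipsoid flattened in depth,
  resting on the retinal surface over the fovea;
* Cloquet's canal (CC), a truncated cone standing on the retina anterior to
  the optic disc;
* optional accessory ellipsoidal cavities;
* an optional narrow PMP–CC connecting canal (a cylinder).

Every primitive has a closed-form volume, so rasterized ground truth can be
checked against analytic values, and the module also supplies high-resolution
quadrature surface areas as an oracle independent of the pipeline's
marching-cubes measurement.

Speckle is modeled as multiplicative gamma noise (shape ``k``, mean 1),
the standard first-order model for fully developed coherent speckle; the
noiseless reflectivity map is multiplied by the noise field and clipped to
[0, 1]. Noise never alters the ground-truth masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .types import OCTVolume, SparseLabelSet, check_plane

__all__ = [
    "HalfEllipsoid",
    "TruncatedCone",
    "Ellipsoid",
    "Canal",
    "PhantomSpec",
    "GroundTruth",
    "RaterErrorModel",
    "generate_phantom",
    "simulate_rater",
    "analytic_surface_area",
]


# --------------------------------------------------------------------------
# geometry primitives (all coordinates/lengths in mm)


@dataclass
class HalfEllipsoid:
    """Half-ellipsoid resting base-down on the plane ``z = base_z``.

    The solid occupies ellipsoid points with ``z <= base_z`` (anterior of the
    base), i.e. the bowl opens toward the retina it sits on. Volume is
    ``2*pi*a*b*c/3``.
    """

    center_xy: Tuple[float, float]
    semi_axes: Tuple[float, float, float]  # a (x), b (y), c (depth)
    base_z: float

    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 2.0 * math.pi * a * b * c / 3.0


@dataclass
class TruncatedCone:
    """Truncated cone with axis along depth, base on ``z = base_z``.

    The base disc (radius ``base_radius``) lies on the retinal surface; the
    apex disc (radius ``apex_radius``) sits ``length`` mm anterior to it.
    Volume is ``pi*L*(R^2 + R*r + r^2)/3``.
    """

    center_xy: Tuple[float, float]
    base_radius: float
    apex_radius: float
    length: float
    base_z: float

    def volume(self) -> float:
        R, r, L = self.base_radius, self.apex_radius, self.length
        return math.pi * L * (R * R + R * r + r * r) / 3.0


@dataclass
class Ellipsoid:
    """Full ellipsoid accessory cavity; volume ``4*pi*a*b*c/3``."""

    center: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]

    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 * math.pi * a * b * c / 3.0


@dataclass
class Canal:
    """Straight cylindrical canal joining two points; volume ``pi*r^2*L``."""

    start: Tuple[float, float, float]
    end: Tuple[float, float, float]
    radius: float

    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))

    def volume(self) -> float:
        return math.pi * self.radius ** 2 * self.length()


# --------------------------------------------------------------------------
# phantom specification


@dataclass
class PhantomSpec:
    """Full description of one synthetic eye.

    Defaults reproduce the study geometry: a 12 x 9 x 2.6 mm field on a
    256 x 192 x 56 grid (near-isotropic ~0.047 mm voxels), fovea and disc on
    the horizontal midline ~4.8 mm apart, the retinal surface at 2.1 mm
    depth, a 3 x 2.5 x 0.8 mm half-ellipsoid PMP and a truncated-cone CC.
    Reflectivities are ordered fluid < gel < retina.
    """

    grid_shape: Tuple[int, int, int] = (256, 192, 56)
    field_extent: Tuple[float, float, float] = (12.0, 9.0, 2.6)
    laterality: str = "right"
    fovea_xy: Tuple[float, float] = (8.4, 4.5)
    disc_xy: Tuple[float, float] = (3.6, 4.5)
    retina_surface_z: float = 2.1
    pmp_geometry: Optional[HalfEllipsoid] = None
    cc_geometry: Optional[TruncatedCone] = None
    accessory_cavities: List[Ellipsoid] = field(default_factory=list)
    connection: Optional[Canal] = None
    gel_intensity: float = 0.45
    fluid_intensity: float = 0.08
    retina_intensity: float = 0.85
    boundary_intensity: Optional[float] = None  # optional hyperreflective cavity wall
    boundary_thickness: float = 0.05
    speckle_shape: Optional[float] = 4.0  # None disables speckle entirely
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError(f"grid shape must be positive, got {self.grid_shape}")
        if not (self.fluid_intensity < self.gel_intensity < self.retina_intensity):
            raise ValueError(
                "reflectivities must satisfy fluid < gel < retina, got "
                f"{self.fluid_intensity}, {self.gel_intensity}, {self.retina_intensity}"
            )
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ValueError("speckle shape parameter must be positive")
        self._check_geometry()

    # -- helpers -----------------------------------------------------------

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return tuple(e / n for e, n in zip(self.field_extent, self.grid_shape))

    def _require_inside(self, lo: Sequence[float], hi: Sequence[float], what: str) -> None:
        ex = self.field_extent
        for axis, (a, b) in enumerate(zip(lo, hi)):
            if a < -1e-9 or b > ex[axis] + 1e-9:
                raise ValueError(
                    f"{what} extends outside the scanned field on axis {axis}: "
                    f"[{a:.3f}, {b:.3f}] mm vs field [0, {ex[axis]}] mm"
                )

    def _check_geometry(self) -> None:
        if self.pmp_geometry is not None:
            g = self.pmp_geometry
            cx, cy = g.center_xy
            a, b, c = g.semi_axes
            self._require_inside(
                (cx - a, cy - b, g.base_z - c), (cx + a, cy + b, g.base_z), "PMP"
            )
        if self.cc_geometry is not None:
            g = self.cc_geometry
            cx, cy = g.center_xy
            R = max(g.base_radius, g.apex_radius)
            self._require_inside(
                (cx - R, cy - R, g.base_z - g.length), (cx + R, cy + R, g.base_z), "CC"
            )
        for i, e in enumerate(self.accessory_cavities):
            lo = tuple(c - s for c, s in zip(e.center, e.semi_axes))
            hi = tuple(c + s for c, s in zip(e.center, e.semi_axes))
            self._require_inside(lo, hi, f"accessory cavity {i}")
        if self.connection is not None:
            k = self.connection
            lo = tuple(min(p, q) - k.radius for p, q in zip(k.start, k.end))
            hi = tuple(max(p, q) + k.radius for p, q in zip(k.start, k.end))
            self._require_inside(lo, hi, "connecting canal")

    def with_default_cavities(self, connection_radius: Optional[float] = 0.25) -> "PhantomSpec":
        """Return a copy with the standard PMP, CC and (optionally) a canal.

        ``connection_radius`` of None omits the canal; the default 0.25 mm
        canal is wide enough to survive the 9x9x9 median filter at the
        default resolution.
        """
        pmp = HalfEllipsoid(self.fovea_xy, (3.0, 2.5, 0.8), self.retina_surface_z)
        cc = TruncatedCone(self.disc_xy, 0.9, 0.4, 1.2, self.retina_surface_z)
        canal = None
        if connection_radius is not None:
            z = self.retina_surface_z - 0.35
            canal = Canal(
                (self.fovea_xy[0], self.fovea_xy[1], z),
                (self.disc_xy[0], self.disc_xy[1], z),
                connection_radius,
            )
        return replace(self, pmp_geometry=pmp, cc_geometry=cc, connection=canal)


@dataclass
class GroundTruth:
    """Analytic ground truth accompanying a phantom volume.

    ``structure_masks`` holds one binary grid per primitive ("PMP", "CC",
    "accessory", "canal"); ``fluid_mask`` is their union.
    ``analytic_volumes`` are the closed-form primitive volumes in mm^3
    (overlap between a canal and the cavities it joins is not subtracted).
    """

    fluid_mask: np.ndarray
    structure_masks: Dict[str, np.ndarray]
    analytic_volumes: Dict[str, float]
    spacing: Tuple[float, float, float]

    def voxel_volume(self, structure: Optional[str] = None) -> float:
        """Rasterized volume in mm^3 of one structure (or the union)."""
        mask = self.fluid_mask if structure is None else self.structure_masks[structure]
        return float(mask.sum()) * float(np.prod(self.spacing))


@dataclass
class RaterErrorModel:
    """Stochastic model of a human annotator labeling every Nth frame.

    ``frame_step`` follows the every-8-to-10-frames manual labeling regime.
    Boundary uncertainty is a per-frame morphological dilation (positive
    draw) or erosion (negative draw) of radius ``|N(0, jitter_sd)|`` rounded
    to whole pixels. ``miss_rate`` is the probability that a small cavity
    cross-section (below ``small_region_px``) is left unlabeled.
    """

    frame_step: int = 9
    boundary_jitter_sd: float = 0.0
    miss_rate: float = 0.0
    small_region_px: int = 200
    seed: int = 0
    rater_id: str = "rater"

    def __post_init__(self) -> None:
        if self.frame_step not in (8, 9, 10):
            raise ValueError(f"frame_step must be 8, 9 or 10, got {self.frame_step}")
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary jitter SD must be >= 0")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must lie in [0, 1]")


# --------------------------------------------------------------------------
# rasterization


def _voxel_centers(spec: PhantomSpec):
    sp = spec.spacing
    xs = (np.arange(spec.grid_shape[0]) + 0.5) * sp[0]
    ys = (np.arange(spec.grid_shape[1]) + 0.5) * sp[1]
    zs = (np.arange(spec.grid_shape[2]) + 0.5) * sp[2]
    return xs[:, None, None], ys[None, :, None], zs[None, None, :]


def _rasterize_half_ellipsoid(spec: PhantomSpec, g: HalfEllipsoid) -> np.ndarray:
    x, y, z = _voxel_centers(spec)
    a, b, c = g.semi_axes
    q = (
        ((x - g.center_xy[0]) / a) ** 2
        + ((y - g.center_xy[1]) / b) ** 2
        + ((z - g.base_z) / c) ** 2
    )
    return (q <= 1.0) & (z <= g.base_z)


def _rasterize_truncated_cone(spec: PhantomSpec, g: TruncatedCone) -> np.ndarray:
    x, y, z = _voxel_centers(spec)
    # local height above the apex-end: 0 at anterior tip, length at the base
    h = z - (g.base_z - g.length)
    frac = np.clip(h / g.length, 0.0, 1.0)
    radius = g.apex_radius + (g.base_radius - g.apex_radius) * frac
    rho2 = (x - g.center_xy[0]) ** 2 + (y - g.center_xy[1]) ** 2
    return (h >= 0.0) & (h <= g.length) & (rho2 <= radius ** 2)


def _rasterize_ellipsoid(spec: PhantomSpec, g: Ellipsoid) -> np.ndarray:
    x, y, z = _voxel_centers(spec)
    a, b, c = g.semi_axes
    q = (
        ((x - g.center[0]) / a) ** 2
        + ((y - g.center[1]) / b) ** 2
        + ((z - g.center[2]) / c) ** 2
    )
    return q <= 1.0


def _rasterize_canal(spec: PhantomSpec, g: Canal) -> np.ndarray:
    x, y, z = _voxel_centers(spec)
    p = np.asarray(g.start, dtype=float)
    d = np.asarray(g.end, dtype=float) - p
    L2 = float(d @ d)
    if L2 == 0.0:
        return np.zeros(spec.grid_shape, dtype=bool)
    # projection parameter of each voxel center onto the axis, clamped to the segment
    t = ((x - p[0]) * d[0] + (y - p[1]) * d[1] + (z - p[2]) * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    dx = x - (p[0] + t * d[0])
    dy = y - (p[1] + t * d[1])
    dz = z - (p[2] + t * d[2])
    return dx * dx + dy * dy + dz * dz <= g.radius ** 2


def generate_phantom(spec: PhantomSpec) -> Tuple[OCTVolume, GroundTruth]:
    """Render a phantom OCT volume and its analytic ground truth.

    The noiseless reflectivity map assigns ``retina_intensity`` to the
    posterior band (``z >= retina_surface_z``), ``gel_intensity`` to the
    vitreous and ``fluid_intensity`` inside cavities, then multiplies by
    gamma-distributed speckle (mean 1, shape ``speckle_shape``) and clips to
    [0, 1]. Identical spec and seed give bit-identical volumes.
    """
    shape = spec.grid_shape
    masks: Dict[str, np.ndarray] = {}
    volumes: Dict[str, float] = {}

    if spec.pmp_geometry is not None:
        masks["PMP"] = _rasterize_half_ellipsoid(spec, spec.pmp_geometry)
        volumes["PMP"] = spec.pmp_geometry.volume()
    if spec.cc_geometry is not None:
        masks["CC"] = _rasterize_truncated_cone(spec, spec.cc_geometry)
        volumes["CC"] = spec.cc_geometry.volume()
    if spec.accessory_cavities:
        acc = np.zeros(shape, dtype=bool)
        vol = 0.0
        for e in spec.accessory_cavities:
            acc |= _rasterize_ellipsoid(spec, e)
            vol += e.volume()
        masks["accessory"] = acc
        volumes["accessory"] = vol
    if spec.connection is not None:
        masks["canal"] = _rasterize_canal(spec, spec.connection)
        volumes["canal"] = spec.connection.volume()

    fluid = np.zeros(shape, dtype=bool)
    for m in masks.values():
        fluid |= m

    _, _, z = _voxel_centers(spec)
    retina = np.broadcast_to(z >= spec.retina_surface_z, shape)

    base = np.full(shape, spec.gel_intensity, dtype=np.float64)
    base[retina] = spec.retina_intensity
    if spec.boundary_intensity is not None and fluid.any():
        # optional hyperreflective gel-fluid interface line
        n_dil = max(1, int(round(spec.boundary_thickness / min(spec.spacing))))
        wall = ndimage.binary_dilation(fluid, iterations=n_dil) & ~fluid & ~retina
        base[wall] = spec.boundary_intensity
    base[fluid] = spec.fluid_intensity

    if spec.speckle_shape is not None:
        rng = np.random.default_rng(spec.seed)
        speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, size=shape)
        base = base * speckle
    intensities = np.clip(base, 0.0, 1.0).astype(np.float32)

    volume = OCTVolume(
        intensities=intensities,
        spacing=spec.spacing,
        laterality=spec.laterality,
        fovea_xy=spec.fovea_xy,
        disc_xy=spec.disc_xy,
    )
    truth = GroundTruth(
        fluid_mask=fluid,
        structure_masks=masks,
        analytic_volumes=volumes,
        spacing=spec.spacing,
    )
    return volume, truth


# --------------------------------------------------------------------------
# simulated raters


def _take_frame(grid: np.ndarray, axis: int, index: int) -> np.ndarray:
    return np.take(grid, index, axis=axis)


def simulate_rater(
    truth: GroundTruth, plane: str, model: RaterErrorModel
) -> SparseLabelSet:
    """Simulate a human annotator sparsely labeling one plane.

    Frames ``0, frame_step, 2*frame_step, ...`` receive a label mask equal to
    the ground-truth cross-section perturbed by a per-frame random dilation
    or erosion (disk radius ``|N(0, jitter_sd)|`` rounded; the sign of the
    draw picks the operation) and by random omission of small
    cross-sections.
    """
    axis = check_plane(plane)
    n_frames = truth.fluid_mask.shape[axis]
    if model.frame_step > n_frames:
        raise ValueError(
            f"frame step {model.frame_step} exceeds the plane's {n_frames} frames"
        )
    rng = np.random.default_rng(model.seed)
    labeled: Dict[int, np.ndarray] = {}
    for idx in range(0, n_frames, model.frame_step):
        section = _take_frame(truth.fluid_mask, axis, idx).copy()
        draw = rng.normal(0.0, model.boundary_jitter_sd) if model.boundary_jitter_sd > 0 else 0.0
        radius = int(round(abs(draw)))
        if radius > 0 and section.any():
            selem = _disk(radius)
            if draw > 0:
                section = ndimage.binary_dilation(section, structure=selem)
            else:
                section = ndimage.binary_erosion(section, structure=selem)
        if model.miss_rate > 0 and section.any():
            lab, n = ndimage.label(section)
            for comp in range(1, n + 1):
                comp_mask = lab == comp
                if comp_mask.sum() < model.small_region_px and rng.random() < model.miss_rate:
                    section &= ~comp_mask
        labeled[idx] = section
    return SparseLabelSet(plane=plane, labeled_frames=labeled, rater_id=model.rater_id)


def _disk(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


# --------------------------------------------------------------------------
# analytic surface areas (quadrature oracle, independent of marching cubes)


def _ellipsoid_patch_area(
    semi_axes: Tuple[float, float, float],
    theta_range: Tuple[float, float],
    n: int,
) -> float:
    """Surface area of an ellipsoid zone via midpoint quadrature.

    Parametrization x=a sin(t)cos(p), y=b sin(t)sin(p), z=c cos(t); the area
    element |r_t x r_p| is integrated on an n x n midpoint grid.
    """
    a, b, c = semi_axes
    t0, t1 = theta_range
    t = t0 + (np.arange(n) + 0.5) * (t1 - t0) / n
    p = (np.arange(n) + 0.5) * (2.0 * math.pi / n)
    T, P = np.meshgrid(t, p, indexing="ij")
    st, ct = np.sin(T), np.cos(T)
    sp, cp = np.sin(P), np.cos(P)
    # cross product of the parametric tangents
    ex = b * c * st * st * cp
    ey = a * c * st * st * sp
    ez = a * b * st * ct
    dA = np.sqrt(ex * ex + ey * ey + ez * ez)
    return float(dA.sum() * (t1 - t0) / n * 2.0 * math.pi / n)


def analytic_surface_area(
    spec: PhantomSpec, structure: str, n_quad: int = 2048
) -> float:
    """Total surface area (mm^2) of one phantom primitive's closed solid.

    Curved parts are obtained by numerical quadrature over the parametric
    surface; flat caps (half-ellipsoid base, cone end discs) are added in
    closed form. This is the oracle the marching-cubes measurement is tested
    against; it never calls the pipeline.
    """
    if structure == "PMP":
        g = spec.pmp_geometry
        if g is None:
            raise ValueError("phantom has no PMP")
        a, b, c = g.semi_axes
        if min(a, b, c) == 0:
            return 0.0
        curved = _ellipsoid_patch_area((a, b, c), (math.pi / 2.0, math.pi), n_quad)
        base = math.pi * a * b
        return curved + base
    if structure == "CC":
        g = spec.cc_geometry
        if g is None:
            raise ValueError("phantom has no CC")
        R, r, L = g.base_radius, g.apex_radius, g.length
        if L == 0 or (R == 0 and r == 0):
            return 0.0
        slant = math.sqrt(L * L + (R - r) ** 2)
        return math.pi * (R + r) * slant + math.pi * (R * R + r * r)
    if structure == "accessory":
        total = 0.0
        for e in spec.accessory_cavities:
            if min(e.semi_axes) == 0:
                continue
            total += _ellipsoid_patch_area(e.semi_axes, (0.0, math.pi), n_quad)
        return total
    if structure == "canal":
        g = spec.connection
        if g is None:
            raise ValueError("phantom has no connecting canal")
        L = g.length()
        return 2.0 * math.pi * g.radius * L + 2.0 * math.pi * g.radius ** 2
    raise ValueError(f"unsupported primitive {structure!r}")
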