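"""Spherical eye model and stereographic projection geometry.

Ultra-widefield angiograms are delivered as stereographic projections of the
retinal sphere onto the plane tangent at the fovea (projection point at the
antipode of the fovea).  For an emmetropic eye of axial length 24 mm the
retina is modelled as a sphere of radius R = 12 mm.  Under this projection a
point at polar angle ``theta`` from the fovea (geodesic distance ``d = R*theta``)
lands at plane radius ``rho = 2 R tan(theta/2)``, and a projected pixel of side
``pixel_pitch`` covers a true retinal area of ``pixel_pitch**2 * cos(theta/2)**4``
square millimetres (the Jacobian of the inverse map).  These two formulas are
all that is needed to convert pixel counts into distortion-corrected physical
areas and to draw fovea-centred zone grids whose radii are geodesic
distances on the eye.

Zones follow the four concentric rings used for regional densitometry:
macular (MR, 0.5-3 mm), near-peripheral (NPR, 3-10 mm), mid-peripheral
(MPR, 10-15 mm) and far-peripheral (FPR, 15 mm out to the gradable
boundary).  The central sub-0.5 mm disc belongs to no named zone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Default ring boundaries (geodesic mm from the fovea).
DEFAULT_ZONE_BOUNDARIES_MM: tuple[float, float, float, float] = (0.5, 3.0, 10.0, 15.0)

#: Integer labels used in zone rasters.
EXCLUDED, MR, NPR, MPR, FPR = 0, 1, 2, 3, 4
ZONE_NAMES: dict[int, str] = {MR: "MR", NPR: "NPR", MPR: "MPR", FPR: "FPR", EXCLUDED: "EXCLUDED"}
ZONE_CODES: dict[str, int] = {v: k for k, v in ZONE_NAMES.items()}


def default_pixel_pitch(grid_width: int = 3900, field_of_view_deg: float = 200.0,
                        sphere_radius_mm: float = 12.0) -> float:
    """Plane pixel pitch (mm/px) so that ``grid_width`` pixels span the given field of view.

    A 200-degree field of view means the projected image reaches polar angle
    100 degrees on either side of the fovea, i.e. plane radius
    ``2 R tan(50 deg)``.  The device calibration is not public, so this
    convention anchors the default scale.
    """
    half_theta = np.deg2rad(field_of_view_deg / 2.0)
    rho_max = 2.0 * sphere_radius_mm * np.tan(half_theta / 2.0)
    return float(2.0 * rho_max / grid_width)


@dataclass(frozen=True)
class EyeModel:
    """Spherical emmetropic eye plus the raster it is imaged onto.

    Parameters
    ----------
    grid_shape
        (rows, cols) of the stereographic raster.
    pixel_pitch
        Millimetres per pixel on the tangent plane at the fovea.
    fovea_pixel
        (row, col) of the fovea, 0-based, pixel centres at integers.  When
        omitted the grid centre is used and a warning is logged, because the
        zone grid must be fovea-centred.
    axial_length
        Axial length in mm; the retinal sphere radius is half of it.
    """

    grid_shape: tuple[int, int]
    pixel_pitch: float
    fovea_pixel: tuple[float, float] | None = None
    axial_length: float = 24.0
    sphere_radius: float = field(init=False)

    def __post_init__(self) -> None:
        if self.axial_length <= 0:
            raise ValueError("axial_length must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "sphere_radius", self.axial_length / 2.0)
        if self.fovea_pixel is None:
            centre = ((self.grid_shape[0] - 1) / 2.0, (self.grid_shape[1] - 1) / 2.0)
            logger.warning("fovea_pixel not given; defaulting to grid centre %s", centre)
            object.__setattr__(self, "fovea_pixel", centre)
        r, c = self.fovea_pixel
        if not (0 <= r < self.grid_shape[0] and 0 <= c < self.grid_shape[1]):
            raise ValueError(f"fovea_pixel {self.fovea_pixel} outside grid {self.grid_shape}")


def plane_radius_from_geodesic(d, model: EyeModel):
    """Forward stereographic map: geodesic distance d (mm) -> plane radius rho (mm).

    rho = 2 R tan(theta/2) with theta = d / R.  Strictly increasing on
    [0, pi*R); d at or beyond the antipode has no projection.
    """
    d = np.asarray(d, dtype=float)
    R = model.sphere_radius
    if np.any(d < 0) or np.any(d >= np.pi * R):
        raise ValueError(f"geodesic distance must lie in [0, pi*R) = [0, {np.pi * R:.4f}) mm")
    theta = d / R
    return 2.0 * R * np.tan(theta / 2.0)


def geodesic_from_plane_radius(rho, model: EyeModel):
    """Inverse stereographic map: plane radius rho (mm) -> geodesic distance (mm)."""
    rho = np.asarray(rho, dtype=float)
    R = model.sphere_radius
    return R * 2.0 * np.arctan(rho / (2.0 * R))


def _plane_radius_raster(model: EyeModel) -> np.ndarray:
    rows, cols = model.grid_shape
    fr, fc = model.fovea_pixel
    rr = np.arange(rows, dtype=float)[:, None] - fr
    cc = np.arange(cols, dtype=float)[None, :] - fc
    return model.pixel_pitch * np.hypot(rr, cc)


def geodesic_distance(pixel: tuple[float, float], model: EyeModel) -> float:
    """Geodesic distance (mm) from the fovea to one pixel."""
    r, c = pixel
    if not (0 <= r < model.grid_shape[0] and 0 <= c < model.grid_shape[1]):
        raise ValueError(f"pixel {pixel} outside grid {model.grid_shape}")
    fr, fc = model.fovea_pixel
    rho = model.pixel_pitch * np.hypot(r - fr, c - fc)
    return float(geodesic_from_plane_radius(rho, model))


def geodesic_map(model: EyeModel) -> np.ndarray:
    """Raster of geodesic distance (mm) from the fovea for every pixel."""
    return np.asarray(geodesic_from_plane_radius(_plane_radius_raster(model), model))


def pixel_area(pixel: tuple[float, float], model: EyeModel) -> float:
    """True retinal area (mm^2) covered by one projected pixel."""
    r, c = pixel
    if not (0 <= r < model.grid_shape[0] and 0 <= c < model.grid_shape[1]):
        raise ValueError(f"pixel {pixel} outside grid {model.grid_shape}")
    fr, fc = model.fovea_pixel
    rho = model.pixel_pitch * np.hypot(r - fr, c - fc)
    theta = 2.0 * np.arctan(rho / (2.0 * model.sphere_radius))
    return float(model.pixel_pitch**2 * np.cos(theta / 2.0) ** 4)


def area_map(model: EyeModel) -> np.ndarray:
    """Per-pixel true retinal area (mm^2): ``pitch^2 * cos^4(theta/2)``.

    The scale factor is 1 at the fovea and falls monotonically with
    eccentricity — a peripheral projected pixel covers *less* retina, the
    inverse of the raw ultra-widefield magnification the projection corrects.
    """
    rho = _plane_radius_raster(model)
    theta = 2.0 * np.arctan(rho / (2.0 * model.sphere_radius))
    return model.pixel_pitch**2 * np.cos(theta / 2.0) ** 4


@dataclass(frozen=True)
class ZonePartition:
    """Fovea-centred concentric-ring labelling of the raster.

    ``labels`` holds the integer codes MR/NPR/MPR/FPR/EXCLUDED.  Pixels
    closer than the innermost boundary, or outside the visible (gradable)
    mask, are EXCLUDED; the FPR runs from the outermost boundary to the
    visible edge.
    """

    labels: np.ndarray
    boundaries_mm: tuple[float, ...]

    def mask(self, zone: int | str) -> np.ndarray:
        code = ZONE_CODES[zone] if isinstance(zone, str) else zone
        return self.labels == code


def assign_zones(model: EyeModel, visible: np.ndarray,
                 boundaries_mm: tuple[float, ...] = DEFAULT_ZONE_BOUNDARIES_MM) -> ZonePartition:
    """Partition the raster into MR/NPR/MPR/FPR by geodesic distance from the fovea."""
    visible = np.asarray(visible, dtype=bool)
    if visible.shape != model.grid_shape:
        raise ValueError(f"visible mask shape {visible.shape} != grid {model.grid_shape}")
    if len(boundaries_mm) != 4 or list(boundaries_mm) != sorted(boundaries_mm):
        raise ValueError("boundaries_mm must be four increasing radii")
    fr, fc = model.fovea_pixel
    if not visible[int(round(fr)), int(round(fc))]:
        warnings.warn("fovea pixel lies outside the visible mask", stacklevel=2)
    d = geodesic_map(model)
    b0, b1, b2, b3 = boundaries_mm
    labels = np.full(model.grid_shape, EXCLUDED, dtype=np.uint8)
    labels[(d >= b0) & (d < b1)] = MR
    labels[(d >= b1) & (d < b2)] = NPR
    labels[(d >= b2) & (d < b3)] = MPR
    labels[d >= b3] = FPR
    labels[~visible] = EXCLUDED
    return ZonePartition(labels=labels, boundaries_mm=tuple(boundaries_mm))


def central_disc_mask(model: EyeModel, visible: np.ndarray,
                      radius_mm: float = DEFAULT_ZONE_BOUNDARIES_MM[0]) -> np.ndarray:
    """Visible pixels inside the sub-0.5 mm disc (counted in totals, in no zone)."""
    return (geodesic_map(model) < radius_mm) & np.asarray(visible, dtype=bool)


def spherical_cap_area(d_mm: float, sphere_radius_mm: float = 12.0) -> float:
    """Closed-form area (mm^2) of a geodesic disc of radius ``d_mm`` on the sphere."""
    R = sphere_radius_mm
    return float(2.0 * np.pi * R**2 * (1.0 - np.cos(d_mm / R)))
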