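"""Vascular area and density accounting.

Per region the pipeline reports the total vascular area (TVA, from the ICGA
mask), the retinal vascular area (RVA, from the FA mask), the choroidal
vascular area CVA = TVA - RVA, and the choroidal vascular density
CVD = 100 * CVA / gradable area.  Regions are the four concentric zones plus
TOTAL, the entire gradable region.  TOTAL includes the central sub-0.5 mm
disc that belongs to no named zone, so the zone CVAs sum to TOTAL minus the
central-disc contribution; this reconciliation is carried in the report.

Areas are physical (mm^2): every counted pixel is weighted by its true
retinal area from the stereographic Jacobian, never by a flat pixel count.
CVA is a scalar area difference per region, mirroring how the densities are
defined; a pixelwise ICGA-minus-FA mask mode is available for callers who
want to see the choroid-only raster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import FPR, MPR, MR, NPR, ZonePartition, central_disc_mask
from .segmentation import TrimMask, VesselMask

REGIONS: tuple[str, ...] = ("MR", "NPR", "MPR", "FPR", "TOTAL")
_ZONE_CODES = {"MR": MR, "NPR": NPR, "MPR": MPR, "FPR": FPR}
_COLUMNS = ("tva_mm2", "rva_mm2", "cva_mm2", "visible_area_mm2", "cvd_pct")


@dataclass(frozen=True)
class VascularMetrics:
    """Region-by-quantity table of TVA/RVA/CVA (mm^2) and CVD (%).

    ``frame`` is indexed by region (MR, NPR, MPR, FPR, TOTAL) with columns
    tva_mm2, rva_mm2, cva_mm2, visible_area_mm2, cvd_pct.
    ``central_disc_cva_mm2`` reconciles the zone sum with TOTAL.
    """

    frame: pd.DataFrame
    central_disc_cva_mm2: float = 0.0
    grader_id: str = "auto"

    def __post_init__(self) -> None:
        missing = set(REGIONS) - set(self.frame.index)
        if missing:
            raise ValueError(f"metrics frame missing regions {sorted(missing)}")

    def __getitem__(self, region: str) -> pd.Series:
        return self.frame.loc[region]

    def cvd(self, region: str = "TOTAL") -> float:
        return float(self.frame.loc[region, "cvd_pct"])

    def to_row(self, eye_id: str) -> pd.Series:
        """Flatten into one wide CSV row per eye."""
        out: dict[str, float | str] = {"eye_id": eye_id, "grader": self.grader_id}
        for region in REGIONS:
            suffix = region.lower() if region != "TOTAL" else "total"
            for col in _COLUMNS:
                out[f"{col.rsplit('_', 1)[0]}_{suffix}"] = float(self.frame.loc[region, col])
        out["visible_area_total"] = float(self.frame.loc["TOTAL", "visible_area_mm2"])
        return pd.Series(out)


def masked_area(mask: np.ndarray | VesselMask, areas: np.ndarray,
                region: np.ndarray | None = None) -> float:
    """Physical area (mm^2) of the vessel pixels inside ``region``."""
    m = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, dtype=bool)
    areas = np.asarray(areas, dtype=float)
    if m.shape != areas.shape:
        raise ValueError(f"mask shape {m.shape} != area map shape {areas.shape}")
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != m.shape:
            raise ValueError(f"region shape {region.shape} != mask shape {m.shape}")
        m = m & region
    return float(areas[m].sum())


def choroidal_area(tva: float, rva: float) -> float:
    """CVA = TVA - RVA.  A negative result flags a data-quality problem
    (independent binarizations can leave RVA > TVA) and is reported as-is."""
    if tva < 0 or rva < 0:
        raise ValueError("areas must be non-negative")
    cva = tva - rva
    if cva < 0:
        warnings.warn(f"negative choroidal area ({cva:.4f} mm^2): RVA exceeds TVA", stacklevel=2)
    return cva


def choroidal_density(cva: float, visible_area: float) -> float:
    """CVD (%) = 100 * CVA / gradable visible area."""
    if visible_area <= 0:
        raise ValueError("visible area must be positive for a density")
    return 100.0 * cva / visible_area


def choroid_only_mask(icga_mask: VesselMask, fa_mask: VesselMask) -> np.ndarray:
    """Pixelwise ICGA-minus-FA raster (optional view; densities use scalar CVA)."""
    return icga_mask.mask & ~fa_mask.mask


def regional_report(fa_mask: VesselMask, icga_mask: VesselMask, areas: np.ndarray,
                    zones: ZonePartition, trim: TrimMask,
                    grader_id: str | None = None) -> VascularMetrics:
    """Per-zone and TOTAL vascular areas and densities for one eye."""
    shapes = {fa_mask.mask.shape, icga_mask.mask.shape, np.asarray(areas).shape,
              zones.labels.shape, trim.visible.shape}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent grids: {shapes}")
    gradable = trim.gradable
    if not gradable.any():
        raise ValueError("gradable region is empty; densities are undefined")

    rows = {}
    for region in ("MR", "NPR", "MPR", "FPR"):
        sel = zones.mask(_ZONE_CODES[region]) & gradable
        rows[region] = _region_row(fa_mask, icga_mask, areas, sel)
    rows["TOTAL"] = _region_row(fa_mask, icga_mask, areas, gradable)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(_COLUMNS)).loc[list(REGIONS)]

    zone_cva = frame.loc[["MR", "NPR", "MPR", "FPR"], "cva_mm2"].sum()
    central_cva = float(frame.loc["TOTAL", "cva_mm2"] - zone_cva)
    gid = grader_id if grader_id is not None else icga_mask.grader_id
    return VascularMetrics(frame=frame, central_disc_cva_mm2=central_cva, grader_id=gid)


def _region_row(fa_mask: VesselMask, icga_mask: VesselMask,
                areas: np.ndarray, sel: np.ndarray) -> list[float]:
    visible_area = float(np.asarray(areas)[sel].sum())
    tva = masked_area(icga_mask, areas, sel)
    rva = masked_area(fa_mask, areas, sel)
    if sel.any() and visible_area <= 0:
        raise ValueError("degenerate region with zero physical area")
    if not sel.any():
        return [0.0, 0.0, 0.0, 0.0, float("nan")]
    cva = choroidal_area(tva, rva)
    return [tva, rva, cva, visible_area, choroidal_density(cva, visible_area)]


def average_graders(m1: VascularMetrics, m2: VascularMetrics) -> VascularMetrics:
    """Field-wise arithmetic mean of two graders' metrics (the reported values)."""
    if list(m1.frame.index) != list(m2.frame.index):
        raise ValueError("grader metrics have different region structure")
    frame = (m1.frame + m2.frame) / 2.0
    return VascularMetrics(frame=frame,
                           central_disc_cva_mm2=(m1.central_disc_cva_mm2
                                                 + m2.central_disc_cva_mm2) / 2.0,
                           grader_id=f"mean({m1.grader_id},{m2.grader_id})")


@dataclass(frozen=True)
class GraderPair:
    """Two independent gradings of one eye plus their average."""

    grader1: VascularMetrics
    grader2: VascularMetrics

    @property
    def averaged(self) -> VascularMetrics:
        return average_graders(self.grader1, self.grader2)
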