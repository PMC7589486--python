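"""Vessel extraction from early-phase FA / ICGA frames.

The chain is the classic bright-vessel recipe: white top-hat with a disc
structuring element to flatten uneven background, global Otsu (or a fixed
cut) to binarize, a connected-component area filter to drop speckle, and a
trim step that clips the mask to the manually outlined gradable region minus
exclusion areas (eyelashes, low-contrast patches).  Everything is
deterministic given the image and the config.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import disk, remove_small_objects, white_tophat


class Modality(str, Enum):
    FA = "FA"
    ICGA = "ICGA"


class ThresholdMethod(str, Enum):
    OTSU = "otsu"
    FIXED = "fixed"


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the segmentation chain.

    tophat_radius
        Disc radius (px) of the white top-hat; must exceed half the widest
        vessel calibre to preserve it.
    threshold_method / fixed_threshold
        Global Otsu on the top-hat output, or a fixed intensity cut.
    min_component_px / connectivity
        Connected components smaller than ``min_component_px`` are treated
        as noise; connectivity 4 or 8.
    """

    tophat_radius: int = 15
    threshold_method: ThresholdMethod = ThresholdMethod.OTSU
    fixed_threshold: float = 0.0
    min_component_px: int = 50
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1")
        if self.min_component_px < 0:
            raise ValueError("min_component_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def with_(self, **kwargs) -> "SegmentationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class VesselMask:
    """Boolean vessel raster from one modality."""

    mask: np.ndarray
    modality: Modality
    grader_id: str = "auto"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class TrimMask:
    """Gradable region: manually outlined visible area minus exclusions."""

    visible: np.ndarray
    exclusions: np.ndarray | None = None

    def __post_init__(self) -> None:
        visible = np.asarray(self.visible, dtype=bool)
        excl = (np.zeros_like(visible) if self.exclusions is None
                else np.asarray(self.exclusions, dtype=bool))
        if excl.shape != visible.shape:
            raise ValueError("visible and exclusions shapes differ")
        object.__setattr__(self, "visible", visible)
        object.__setattr__(self, "exclusions", excl)

    @property
    def gradable(self) -> np.ndarray:
        return self.visible & ~self.exclusions


def tophat_filter(image: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat: image minus its opening with a disc of ``radius`` px.

    Non-negative everywhere; flat backgrounds map to zero; bright structures
    too thin to contain the disc are passed through.
    """
    image = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius > min(image.shape) / 2:
        raise ValueError(f"tophat radius {radius} too large for grid {image.shape}")
    return white_tophat(image, footprint=disk(radius))


def binarize(image: np.ndarray, config: SegmentationConfig,
             modality: Modality = Modality.ICGA, grader_id: str = "auto") -> VesselMask:
    """Threshold an (enhanced) intensity raster into a vessel mask."""
    image = np.asarray(image, dtype=float)
    if config.threshold_method is ThresholdMethod.OTSU:
        if np.ptp(image) == 0:
            raise ValueError(
                "Otsu threshold undefined on a constant image; use threshold_method='fixed'")
        thresh = threshold_otsu(image)
    else:
        thresh = config.fixed_threshold
    return VesselMask(mask=image > thresh, modality=modality, grader_id=grader_id)


def remove_noise(mask: VesselMask, min_component_px: int, connectivity: int = 8) -> VesselMask:
    """Drop connected components smaller than ``min_component_px`` pixels."""
    if min_component_px <= 1:
        return mask
    # skimage connectivity: 1 = 4-neighbour, 2 = 8-neighbour; components with
    # fewer than min_component_px pixels are dropped (max_size is inclusive)
    conn = 1 if connectivity == 4 else 2
    cleaned = remove_small_objects(mask.mask, max_size=min_component_px - 1, connectivity=conn)
    return VesselMask(mask=cleaned, modality=mask.modality, grader_id=mask.grader_id)


def apply_trim(mask: VesselMask, trim: TrimMask) -> VesselMask:
    """Clip the vessel mask to the gradable region (visible AND NOT exclusions)."""
    if trim.visible.shape != mask.mask.shape:
        raise ValueError(f"trim shape {trim.visible.shape} != mask shape {mask.mask.shape}")
    return VesselMask(mask=mask.mask & trim.gradable,
                      modality=mask.modality, grader_id=mask.grader_id)


def segment(image: np.ndarray, config: SegmentationConfig, trim: TrimMask | None = None,
            modality: Modality = Modality.ICGA, grader_id: str = "auto") -> VesselMask:
    """Full chain: top-hat -> binarize -> component filter -> trim."""
    enhanced = tophat_filter(image, config.tophat_radius)
    mask = binarize(enhanced, config, modality=modality, grader_id=grader_id)
    mask = remove_noise(mask, config.min_component_px, config.connectivity)
    if trim is not None:
        mask = apply_trim(mask, trim)
    return mask
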