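"""Raster and config IO: grayscale TIFF/PNG frames, 0/255 mask images, YAML/TOML configs."""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image


def read_gray(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF or PNG as a float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(float)


def write_gray(path: str | Path, image: np.ndarray) -> None:
    """Write a float raster as TIFF (float32) or 8-bit PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        Image.fromarray(np.clip(image, 0, 255).astype(np.uint8)).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask stored as 0/255 PNG or 0/1 TIFF."""
    return read_gray(path) > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.astype(np.uint8))
    else:
        Image.fromarray((mask * 255).astype(np.uint8)).save(path)


def load_config(path: str | Path) -> dict:
    """Load a TOML or YAML key-value config."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)
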