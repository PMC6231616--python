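"""Image I/O and validation helpers.

All processing happens on 2-D (grayscale) or H x W x 3 (layered) float arrays
with intensities in [0, 1].  8-bit files map via ``v / 255`` on read and
``round(v * 255)`` on write, so filter parameters expressed on the unit
intensity scale are independent of bit depth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_gray", "write_image", "check_gray", "check_layered"]


def check_gray(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Validate a 2-D intensity field in [0, 1]; returns it as float64."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"{name} must be a non-empty 2-D array, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite intensities")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError(f"{name} intensities must lie in [0, 1]")
    return img


def check_layered(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Validate an H x W x 3 layered image in [0, 1]; returns it as float64."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{name} must have shape (H, W, 3), got {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite intensities")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError(f"{name} intensities must lie in [0, 1]")
    return img


def read_gray(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF into a [0, 1] float array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] image as 8-bit grayscale (2-D) or 24-bit RGB (H,W,3) PNG/TIFF."""
    arr = np.asarray(img, dtype=np.float64)
    data = np.rint(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    if arr.ndim == 2:
        Image.fromarray(data, mode="L").save(path)
    elif arr.ndim == 3 and arr.shape[2] == 3:
        Image.fromarray(data, mode="RGB").save(path)
    else:
        raise ValueError(f"cannot write image of shape {arr.shape}")
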