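"""Grayscale image loading, normalization and saving.

B-mode ultrasound frames arrive as 8-bit PNG or BMP files (sometimes saved as
RGB by the scanner export); everything downstream works on 2-D float fields
normalized to [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["load_gray", "normalize", "save_gray", "as_gray"]

#: ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def as_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, 3|4]) array to a 2-D float64 field by luminance."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 3:
        a = a[..., :3] @ _LUMA
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D or RGB image, got shape {arr.shape}")
    return a


def normalize(image: np.ndarray) -> np.ndarray:
    """Min-max rescale a 2-D field to [0, 1]; a constant field maps to 0."""
    a = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def load_gray(path: str | Path) -> np.ndarray:
    """Load a PNG/BMP file as a normalized 2-D field in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    return normalize(as_gray(arr))


def save_gray(path: str | Path, image: np.ndarray, bitdepth: int = 8) -> None:
    """Write a [0, 1] field as an 8-bit (PNG/BMP) or 16-bit (PNG) grayscale file."""
    a = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if bitdepth == 8:
        Image.fromarray(np.round(a * 255).astype(np.uint8)).save(path)
    elif bitdepth == 16:
        Image.fromarray(np.round(a * 65535).astype(np.uint16)).save(path)
    else:
        raise ValueError("bitdepth must be 8 or 16")
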