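"""Contourlet decomposition: Laplacian pyramid + directional filter bank.

Pyramid levels are labelled 1 (coarsest directional level) to ``depth``
(finest, full input extent).  Each level's bandpass image can be run through
the DFB at more than one directional resolution -- the feature-extraction
band set uses 4- and 8-direction splits at level 2, 8/16 at level 3 and
16/32 at level 4 -- so a level maps direction-count -> band list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..keys import SubbandKey
from .dfb import dfb_decompose, dfb_reconstruct
from .pyramid import pyramid_decompose, pyramid_reconstruct

__all__ = [
    "ContourletDecomposition",
    "contourlet_decompose",
    "contourlet_reconstruct",
    "DEFAULT_DIRECTIONS",
]

#: Direction counts per pyramid level (coarsest first) exposing the six
#: feature bands P2D4, P2D8, P3D8, P3D16, P4D16 and P4D32.
DEFAULT_DIRECTIONS: tuple[tuple[int, ...], ...] = ((4,), (4, 8), (8, 16), (16, 32))


@dataclass
class ContourletDecomposition:
    """Lowpass residual plus per-level directional band lists."""

    lowpass: np.ndarray
    levels: dict[int, dict[int, list[np.ndarray]]] = field(default_factory=dict)
    shape: tuple[int, int] = (0, 0)

    def bands(self, level: int, n_directions: int) -> list[np.ndarray]:
        try:
            return self.levels[level][n_directions]
        except KeyError:
            raise KeyError(
                f"P{level}D{n_directions} not present in this decomposition"
            ) from None

    def get(self, key: SubbandKey) -> np.ndarray:
        if key.transform != "contourlet":
            raise KeyError(f"{key} is not a contourlet key")
        bands = self.bands(key.level, key.n_directions)
        if key.index is None:
            raise KeyError(f"{key} has no band index; resolve it via select_subbands")
        return bands[key.index]


def _normalize_directions(directions_per_level) -> list[tuple[int, ...]]:
    out = []
    for entry in directions_per_level:
        counts = (entry,) if np.isscalar(entry) else tuple(entry)
        for d in counts:
            d = int(d)
            if d < 2 or d & (d - 1):
                raise ValueError(f"direction count {d} is not a power of 2 (>= 2)")
        out.append(tuple(int(d) for d in counts))
    return out


def contourlet_decompose(
    image: np.ndarray,
    directions_per_level=DEFAULT_DIRECTIONS,
) -> ContourletDecomposition:
    """Decompose a [0, 1] image into lowpass + directional sub-bands.

    ``directions_per_level`` lists, coarsest level first, the direction
    count(s) at which each pyramid level's bandpass is split.
    """
    x = np.asarray(image, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains non-finite values")
    if min(x.shape) < 32:
        raise ValueError(f"image {x.shape} too small; need at least 32x32")
    dirs = _normalize_directions(directions_per_level)
    depth = len(dirs)
    if x.shape[0] % 2**depth or x.shape[1] % 2**depth:
        raise ValueError(f"image shape {x.shape} not divisible by 2^{depth}")
    lowpass, bandpasses = pyramid_decompose(x, depth)  # fine -> coarse
    dec = ContourletDecomposition(lowpass=lowpass, shape=x.shape)
    for level_label, counts in enumerate(dirs, start=1):
        bp = bandpasses[depth - level_label]
        dec.levels[level_label] = {
            d: dfb_decompose(bp, int(np.log2(d))) for d in counts
        }
    return dec


def contourlet_reconstruct(dec: ContourletDecomposition) -> np.ndarray:
    """Invert :func:`contourlet_decompose` (exact for any band content).

    When a level was split at several directional resolutions the first
    (coarsest) split is used; the others are redundant views of the same
    bandpass image.
    """
    depth = len(dec.levels)
    bandpasses = []
    for level_label in sorted(dec.levels, reverse=True):  # fine -> coarse
        by_count = dec.levels[level_label]
        d = min(by_count)
        bands = by_count[d]
        shapes = {b.shape for b in bands}
        if len({(s[0] * s[1]) for s in shapes}) != 1:
            raise ValueError(f"inconsistent band shapes at level {level_label}")
        bandpasses.append(dfb_reconstruct(bands, int(np.log2(d))))
    return pyramid_reconstruct(dec.lowpass, bandpasses)
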