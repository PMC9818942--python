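"""Multiresolution transforms: contourlet and curvelet decompositions.

The six feature sub-bands used throughout the pipeline are P2D4, P2D8,
P3D8, P3D16, P4D16, P4D32 (contourlet) and S2A16, S3A32, S4A32, S5A16,
S5A32, S5A64 (curvelet); :func:`select_subbands` resolves those names to
concrete coefficient images, picking the largest band within a level when
the key does not pin a band index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..keys import SubbandKey, default_contourlet_keys, default_curvelet_keys
from .contourlet import (
    DEFAULT_DIRECTIONS,
    ContourletDecomposition,
    contourlet_decompose,
    contourlet_reconstruct,
)
from .curvelet import (
    DEFAULT_ANGLES,
    CurveletDecomposition,
    curvelet_decompose,
    curvelet_reconstruct,
)

__all__ = [
    "SubbandImage",
    "SubbandKey",
    "ContourletDecomposition",
    "CurveletDecomposition",
    "contourlet_decompose",
    "contourlet_reconstruct",
    "curvelet_decompose",
    "curvelet_reconstruct",
    "select_subbands",
    "decompose",
    "default_contourlet_keys",
    "default_curvelet_keys",
    "DEFAULT_DIRECTIONS",
    "DEFAULT_ANGLES",
]


@dataclass
class SubbandImage:
    """One sub-band's real coefficient field.

    Contourlet coefficients are signed; curvelet entries are coefficient
    magnitudes (hence nonnegative).
    """

    key: SubbandKey
    coeffs: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.coeffs.shape


def _resolve_index(bands: list[np.ndarray], key: SubbandKey) -> int:
    if key.index is not None:
        if key.index >= len(bands):
            raise KeyError(f"{key}: index out of range")
        return key.index
    # default: the largest band; ties broken toward the squarest, then lowest index
    def score(i):
        h, w = bands[i].shape[:2]
        return (h * w, min(h, w), -i)

    return max(range(len(bands)), key=score)


def select_subbands(dec, keys: list[SubbandKey]) -> list[SubbandImage]:
    """Resolve ``keys`` against a decomposition, in key order.

    Curvelet wedges are returned as magnitude fields; contourlet bands keep
    their sign.  Unresolvable keys raise ``KeyError`` naming the key.
    """
    out = []
    for key in keys:
        if isinstance(dec, ContourletDecomposition):
            if key.transform != "contourlet":
                raise KeyError(f"{key}: not a contourlet key")
            try:
                bands = dec.bands(key.level, key.n_directions)
            except KeyError:
                raise KeyError(f"{key.short_name} not available in this decomposition") from None
            idx = _resolve_index(bands, key)
            resolved = SubbandKey("contourlet", key.level, key.n_directions, idx)
            out.append(SubbandImage(resolved, np.asarray(bands[idx], dtype=np.float64)))
        elif isinstance(dec, CurveletDecomposition):
            if key.transform != "curvelet":
                raise KeyError(f"{key}: not a curvelet key")
            group = dec.wedges.get((key.level, key.n_directions))
            if group is None:
                raise KeyError(f"{key.short_name} not available in this decomposition")
            idx = _resolve_index(group, key)
            resolved = SubbandKey("curvelet", key.level, key.n_directions, idx)
            out.append(SubbandImage(resolved, np.abs(group[idx])))
        else:
            raise TypeError(f"unsupported decomposition type {type(dec).__name__}")
    return out


def decompose(image: np.ndarray, transform: str):
    """Decompose with the default configuration of the named transform."""
    if transform == "contourlet":
        return contourlet_decompose(image, DEFAULT_DIRECTIONS)
    if transform == "curvelet":
        return curvelet_decompose(image, 5, DEFAULT_ANGLES)
    raise ValueError(f"unknown transform {transform!r}")
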