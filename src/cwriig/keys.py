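"""Sub-band addressing for contourlet and curvelet decompositions.

A sub-band is addressed by the transform it came from, its pyramid level
(contourlet) or scale (curvelet), the number of directions/angles into which
that level was split, and the index of the band within the split.  The
conventional short names are ``P<level>D<dirs>`` for contourlet bands and
``S<scale>A<angles>`` for curvelet wedges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "SubbandKey",
    "CONTOURLET_KEYS",
    "CURVELET_KEYS",
    "default_contourlet_keys",
    "default_curvelet_keys",
]

_KEY_RE = re.compile(r"^(?:P(?P<p>\d+)D(?P<d>\d+)|S(?P<s>\d+)A(?P<a>\d+))$")


@dataclass(frozen=True, order=True)
class SubbandKey:
    """Address of one directional sub-band.

    Parameters
    ----------
    transform:
        ``"contourlet"`` or ``"curvelet"``.
    level:
        Contourlet pyramid level (1 = coarsest directional level) or
        curvelet scale (1 = coarse isotropic square).
    n_directions:
        Number of directional bands (contourlet) or angular wedges
        (curvelet) the level was split into.
    index:
        Which band within the split, ``0 <= index < n_directions``.
        ``None`` means "the default band for this level", resolved by
        :func:`cwriig.transforms.select_subbands` to the largest band.
    """

    transform: str
    level: int
    n_directions: int
    index: int | None = None

    def __post_init__(self) -> None:
        if self.transform not in ("contourlet", "curvelet"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.transform == "contourlet":
            if self.n_directions < 2 or self.n_directions & (self.n_directions - 1):
                raise ValueError("contourlet direction count must be a power of 2, >= 2")
        else:
            if self.level > 1 and self.n_directions % 4:
                raise ValueError("curvelet angle count must be divisible by 4")
        if self.index is not None and not 0 <= self.index < max(self.n_directions, 1):
            raise ValueError(f"index {self.index} out of range for {self.short_name}")

    @property
    def short_name(self) -> str:
        letter = ("P", "D") if self.transform == "contourlet" else ("S", "A")
        return f"{letter[0]}{self.level}{letter[1]}{self.n_directions}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        idx = "" if self.index is None else f"[{self.index}]"
        return self.short_name + idx

    @classmethod
    def from_name(cls, name: str, index: int | None = None) -> "SubbandKey":
        """Parse a short name like ``"P2D4"`` or ``"S5A64"``."""
        m = _KEY_RE.match(name.strip())
        if not m:
            raise ValueError(f"cannot parse sub-band name {name!r}")
        if m.group("p") is not None:
            return cls("contourlet", int(m.group("p")), int(m.group("d")), index)
        return cls("curvelet", int(m.group("s")), int(m.group("a")), index)


#: The six contourlet bands used for feature extraction.
CONTOURLET_KEYS = ("P2D4", "P2D8", "P3D8", "P3D16", "P4D16", "P4D32")
#: The six curvelet wedges used for feature extraction.
CURVELET_KEYS = ("S2A16", "S3A32", "S4A32", "S5A16", "S5A32", "S5A64")


def default_contourlet_keys() -> list[SubbandKey]:
    """The six default contourlet sub-band keys (band index left for selection)."""
    return [SubbandKey.from_name(n) for n in CONTOURLET_KEYS]


def default_curvelet_keys() -> list[SubbandKey]:
    """The six default curvelet sub-band keys (wedge index left for selection)."""
    return [SubbandKey.from_name(n) for n in CURVELET_KEYS]
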