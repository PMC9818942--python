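"""Curvelet-style tight frame via smooth polar-like tiling of the FFT plane.

Scales are dyadic coronae in the max-norm radius (concentric squares, the
Cartesian analog of the polar tiling); each corona is cut into equiangular
wedges with smoothly overlapping windows.  The window stack is normalized so
that the squared windows sum to exactly one at every frequency, which makes
the transform a tight frame: coefficient energy equals image energy and
reconstruction is exact, both to floating-point rounding.

Each wedge's windowed spectrum is cropped to its (axis-aligned) bounding
box -- zero-padded up to a minimum extent so that 13x13 parameter-mapping
windows always fit -- and inverse-FFT'd with orthonormal scaling, so wedge
coefficient arrays shrink with scale like in the wrapping construction,
at the price of a small redundancy instead of modular wrapping.

A corona may be analyzed at several angular resolutions at once (the
feature set uses 16, 32 and 64 angles at scale 5); each angular group is
normalized independently, so any single group per scale forms a tight frame
and reconstruction uses the first group of each scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..keys import SubbandKey

__all__ = [
    "CurveletDecomposition",
    "curvelet_decompose",
    "curvelet_reconstruct",
    "DEFAULT_ANGLES",
]

#: Angle counts for scales 2..5 exposing S2A16, S3A32, S4A32, S5A16/32/64.
DEFAULT_ANGLES: tuple[tuple[int, ...], ...] = ((16,), (32,), (32,), (16, 32, 64))

#: Minimum wedge coefficient-array extent (so sliding 13x13 windows fit).
MIN_WEDGE_SIZE = 18


def _ramp(t: np.ndarray) -> np.ndarray:
    """Smooth amplitude ramp: 1 at t<=0, cos quarter-wave down to 0 at t>=1."""
    return np.cos(0.5 * np.pi * np.clip(t, 0.0, 1.0))


@dataclass
class _Wedge:
    rows: slice
    cols: slice
    window: np.ndarray  # real window on the cropped box
    pad: tuple[int, int]  # zero-padding appended (bottom, right)


@dataclass
class _Plan:
    shape: tuple[int, int]
    coarse: _Wedge
    groups: dict[tuple[int, int], list[_Wedge]]  # (scale, n_angles) -> wedges


@dataclass
class CurveletDecomposition:
    """Coarse complex band plus per-(scale, angle-count) wedge coefficients."""

    coarse: np.ndarray
    wedges: dict[tuple[int, int], list[np.ndarray]] = field(default_factory=dict)
    shape: tuple[int, int] = (0, 0)
    n_scales: int = 0

    def get(self, key: SubbandKey) -> np.ndarray:
        if key.transform != "curvelet":
            raise KeyError(f"{key} is not a curvelet key")
        group = self.wedges.get((key.level, key.n_directions))
        if group is None:
            raise KeyError(f"S{key.level}A{key.n_directions} not present in this decomposition")
        if key.index is None:
            raise KeyError(f"{key} has no wedge index; resolve it via select_subbands")
        return group[key.index]

    def energy(self) -> float:
        """Total squared coefficient magnitude, counting each corona once."""
        total = float(np.sum(np.abs(self.coarse) ** 2))
        seen: set[int] = set()
        for (scale, _), group in sorted(self.wedges.items()):
            if scale in seen:
                continue
            seen.add(scale)
            total += sum(float(np.sum(np.abs(c) ** 2)) for c in group)
        return total


_PLAN_CACHE: dict[tuple, _Plan] = {}


def _crop(window: np.ndarray) -> _Wedge:
    mask = window > 1e-12
    r = np.flatnonzero(mask.any(axis=1))
    c = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(r[0]), int(r[-1]) + 1
    c0, c1 = int(c[0]), int(c[-1]) + 1
    n1, n2 = window.shape
    pad_r = max(0, min(MIN_WEDGE_SIZE, n1) - (r1 - r0))
    pad_c = max(0, min(MIN_WEDGE_SIZE, n2) - (c1 - c0))
    return _Wedge(slice(r0, r1), slice(c0, c1), window[r0:r1, c0:c1].copy(), (pad_r, pad_c))


def _build_plan(shape: tuple[int, int], n_scales: int,
                angles: tuple[tuple[int, ...], ...]) -> _Plan:
    n1, n2 = shape
    u = (np.arange(n1) - n1 // 2) / (n1 / 2.0)
    v = (np.arange(n2) - n2 // 2) / (n2 / 2.0)
    U, V = u[:, None], v[None, :]
    rho = np.maximum(np.abs(U), np.abs(V))
    theta = np.arctan2(np.broadcast_to(V, (n1, n2)), np.broadcast_to(U, (n1, n2)))

    J = n_scales
    radii = [2.0 ** (j - J) for j in range(1, J + 1)]  # r_1 .. r_J (=1)
    radial = []
    r1 = radii[0]
    radial.append(_ramp((rho - r1 / 2) / (r1 / 2)))  # coarse square
    for j in range(2, J + 1):
        rlo = radii[j - 2]
        up = _ramp((rlo - rho) / (rlo / 2))  # rises over [rlo/2, rlo]
        if j < J:
            down = _ramp((rho - rlo) / rlo)  # falls over [rlo, 2*rlo]
        else:
            down = np.ones_like(rho)  # finest corona reaches the grid corners
        radial.append(up * down)
    norm = np.sqrt(sum(R**2 for R in radial))
    radial = [R / norm for R in radial]

    groups: dict[tuple[int, int], list[_Wedge]] = {}
    for scale, counts in enumerate(angles, start=2):
        R = radial[scale - 1]
        for L in counts:
            t = theta * (L / (2 * np.pi))  # wedge units; nominal edges at +/-0.5
            wins = []
            for ell in range(L):
                center = -L / 2 + ell + 0.5
                d = (t - center + L / 2) % L - L / 2
                wins.append(np.where(np.abs(d) < 1.0, np.cos(0.5 * np.pi * d) ** 2, 0.0))
            anorm = np.sqrt(sum(A**2 for A in wins))
            groups[(scale, L)] = [_crop(R * A / anorm) for A in wins]
    return _Plan(shape=shape, coarse=_crop(radial[0]), groups=groups)


def _get_plan(shape, n_scales, angles) -> _Plan:
    key = (shape, n_scales, angles)
    if key not in _PLAN_CACHE:
        if len(_PLAN_CACHE) > 8:
            _PLAN_CACHE.clear()
        _PLAN_CACHE[key] = _build_plan(shape, n_scales, angles)
    return _PLAN_CACHE[key]


def _normalize_angles(n_scales: int, angles_per_scale) -> tuple[tuple[int, ...], ...]:
    if len(angles_per_scale) != n_scales - 1:
        raise ValueError(
            f"need angle counts for scales 2..{n_scales}, got {len(angles_per_scale)} entries"
        )
    out = []
    for entry in angles_per_scale:
        counts = (entry,) if np.isscalar(entry) else tuple(entry)
        for L in counts:
            if int(L) % 4:
                raise ValueError(f"angle count {L} not divisible by 4")
        out.append(tuple(int(L) for L in counts))
    return tuple(out)


def _analyze(X: np.ndarray, w: _Wedge) -> np.ndarray:
    B = X[w.rows, w.cols] * w.window
    if w.pad != (0, 0):
        B = np.pad(B, ((0, w.pad[0]), (0, w.pad[1])))
    return np.fft.ifft2(B, norm="ortho")


def curvelet_decompose(
    image: np.ndarray,
    n_scales: int = 5,
    angles_per_scale=DEFAULT_ANGLES,
) -> CurveletDecomposition:
    """Decompose a real image into coarse + complex wedge coefficients."""
    x = np.asarray(image, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains non-finite values")
    if n_scales < 2:
        raise ValueError("n_scales must be >= 2")
    if min(x.shape) < 2 ** (n_scales + 1):
        raise ValueError(f"image {x.shape} too small for {n_scales} scales")
    angles = _normalize_angles(n_scales, angles_per_scale)
    plan = _get_plan(x.shape, n_scales, angles)
    X = np.fft.fftshift(np.fft.fft2(x, norm="ortho"))
    dec = CurveletDecomposition(
        coarse=_analyze(X, plan.coarse), shape=x.shape, n_scales=n_scales
    )
    for gk, wedges in plan.groups.items():
        dec.wedges[gk] = [_analyze(X, w) for w in wedges]
    return dec


def curvelet_reconstruct(dec: CurveletDecomposition) -> np.ndarray:
    """Invert :func:`curvelet_decompose` exactly.

    Uses the first angular group of each scale; additional groups are
    redundant views of the same corona.
    """
    angles = []
    by_scale: dict[int, list[int]] = {}
    for (scale, L) in sorted(dec.wedges):
        by_scale.setdefault(scale, []).append(L)
    for scale in range(2, dec.n_scales + 1):
        if scale not in by_scale:
            raise ValueError(f"scale {scale} missing from decomposition")
        angles.append(tuple(by_scale[scale]))
    plan = _get_plan(dec.shape, dec.n_scales, tuple(angles))

    Xrec = np.zeros(dec.shape, dtype=complex)

    def _paste(coeffs: np.ndarray, w: _Wedge) -> None:
        B = np.fft.fft2(coeffs, norm="ortho")
        h = w.rows.stop - w.rows.start
        wd = w.cols.stop - w.cols.start
        Xrec[w.rows, w.cols] += w.window * B[:h, :wd]

    _paste(dec.coarse, plan.coarse)
    for scale, counts in by_scale.items():
        L = counts[0]
        for coeffs, w in zip(dec.wedges[(scale, L)], plan.groups[(scale, L)]):
            _paste(coeffs, w)
    return np.real(np.fft.ifft2(np.fft.ifftshift(Xrec), norm="ortho"))
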