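"""Laplacian pyramid with exact reconstruction.

Reduce/expand use the classic Burt-Adelson 5-tap kernel [1, 4, 6, 4, 1]/16
with periodic boundary handling.  Two properties matter downstream:

* reconstruction is structural: the bandpass level is defined as
  ``x - expand(reduce(x))``, so ``expand(low) + bandpass`` recovers ``x``
  exactly whatever the filters are;
* the kernel is DC-interpolating (its even and odd polyphase components both
  sum to 1/2), so a constant image passes through ``expand(reduce(.))``
  unchanged and every bandpass level of a constant image is exactly zero.
"""

from __future__ import annotations

import numpy as np

__all__ = ["reduce_once", "expand_once", "pyramid_decompose", "pyramid_reconstruct"]

_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _filter_axis(x: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    """Periodic (circular) separable convolution along one axis."""
    n = x.shape[axis]
    k = len(kernel) // 2
    idx = (np.arange(-k, n + k)) % n
    xp = np.take(x, idx, axis=axis)
    out = np.zeros_like(x)
    sl = [slice(None)] * x.ndim
    for i, c in enumerate(kernel):
        sl[axis] = slice(i, i + n)
        out += c * xp[tuple(sl)]
    return out


def _smooth(x: np.ndarray, gain: float = 1.0) -> np.ndarray:
    return _filter_axis(_filter_axis(x, _KERNEL * gain, 0), _KERNEL * gain, 1)


def reduce_once(x: np.ndarray) -> np.ndarray:
    """Lowpass filter and downsample by 2 in both axes (periodic)."""
    if x.shape[0] % 2 or x.shape[1] % 2:
        raise ValueError(f"image shape {x.shape} not divisible by 2")
    return _smooth(x)[::2, ::2]


def expand_once(x: np.ndarray) -> np.ndarray:
    """Upsample by 2 in both axes and interpolate (periodic)."""
    up = np.zeros((2 * x.shape[0], 2 * x.shape[1]), dtype=x.dtype)
    up[::2, ::2] = x
    return _smooth(up, gain=2.0)


def pyramid_decompose(x: np.ndarray, depth: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Split ``x`` into a lowpass residual and ``depth`` bandpass levels.

    Returns ``(lowpass, bandpasses)`` with bandpasses ordered fine -> coarse;
    ``bandpasses[0]`` has the full input extent.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if x.shape[0] % 2**depth or x.shape[1] % 2**depth:
        raise ValueError(f"shape {x.shape} not divisible by 2^{depth}")
    bands = []
    cur = np.asarray(x, dtype=np.float64)
    for _ in range(depth):
        low = reduce_once(cur)
        bands.append(cur - expand_once(low))
        cur = low
    return cur, bands


def pyramid_reconstruct(lowpass: np.ndarray, bandpasses: list[np.ndarray]) -> np.ndarray:
    """Exact inverse of :func:`pyramid_decompose`."""
    cur = lowpass
    for band in reversed(bandpasses):
        if band.shape != tuple(2 * s for s in cur.shape):
            raise ValueError("inconsistent band shapes in pyramid reconstruction")
        cur = expand_once(cur) + band
    return cur
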