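"""Directional filter bank built entirely from invertible (ladder) steps.

The classic contourlet DFB is a binary tree of two-channel fan filter
banks realized with quincunx sampling.  Here every stage is written as a
lifting (ladder) scheme -- a parity-based coset split (a bijection)
followed by predict/update steps -- so analysis and synthesis are exact
mutual inverses to floating-point rounding, independent of how
frequency-selective the predictors are.  All index maps are local (at most
one-pixel parity offsets), so sub-band samples stay spatially coherent
with the input: a lesion keeps its shape in every band, which the
parametric mapping downstream depends on.

Stage layout for ``n`` tree levels (2^n bands) on an H x W input:

* level 1: fan split along columns (bands H x W/2),
* level 2: conjugate fan split along rows (bands H/2 x W/2),
* levels >= 3: the first half of the tree keeps splitting rows with a 1-D
  lifting wavelet, the second half splits columns, giving the familiar
  ``H/2^(n-1) x W/2`` and ``H/2 x W/2^(n-1)`` band families.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dfb_decompose", "dfb_reconstruct", "dfb_band_shapes"]


# ---------------------------------------------------------------- fan stage

def _mod_rows(x: np.ndarray) -> np.ndarray:
    s = np.ones(x.shape[0]) - 2.0 * (np.arange(x.shape[0]) % 2)
    return x * s[:, None]


def _parity_roll(a: np.ndarray, even_shift: int) -> np.ndarray:
    """Roll even rows by ``even_shift`` and odd rows by ``-even_shift`` (axis 1)."""
    out = np.empty_like(a)
    out[::2] = np.roll(a[::2], even_shift, axis=1)
    out[1::2] = np.roll(a[1::2], -even_shift, axis=1)
    return out


def _fan_split_w(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-channel fan filter bank halving the column count (local cosets).

    Coset 0 holds pixels with even i+j, coset 1 the rest; the diamond
    predict/update pair averages the four quincunx neighbours.  Row
    modulation converts the diamond split into the fan split.
    """
    h, w = x.shape
    if w % 2:
        raise ValueError(f"width {w} not even; directional depth too large")
    x = _mod_rows(x)  # fan <-> diamond modulation
    c0 = np.empty((h, w // 2), dtype=x.dtype)
    c1 = np.empty((h, w // 2), dtype=x.dtype)
    c0[::2], c0[1::2] = x[::2, 0::2], x[1::2, 1::2]
    c1[::2], c1[1::2] = x[::2, 1::2], x[1::2, 0::2]
    # horizontal neighbours of a c1 site: c0 itself and c0 rolled toward it
    # (direction alternates with row parity); vertical neighbours align.
    pred = (c0 + _parity_roll(c0, -1) + np.roll(c0, 1, 0) + np.roll(c0, -1, 0)) / 4.0
    d = c1 - pred
    upd = (d + _parity_roll(d, 1) + np.roll(d, 1, 0) + np.roll(d, -1, 0)) / 8.0
    return c0 + upd, d


def _fan_merge_w(s: np.ndarray, d: np.ndarray) -> np.ndarray:
    h, wh = s.shape
    upd = (d + _parity_roll(d, 1) + np.roll(d, 1, 0) + np.roll(d, -1, 0)) / 8.0
    c0 = s - upd
    pred = (c0 + _parity_roll(c0, -1) + np.roll(c0, 1, 0) + np.roll(c0, -1, 0)) / 4.0
    c1 = d + pred
    x = np.empty((h, 2 * wh), dtype=s.dtype)
    x[::2, 0::2], x[1::2, 1::2] = c0[::2], c0[1::2]
    x[::2, 1::2], x[1::2, 0::2] = c1[::2], c1[1::2]
    return _mod_rows(x)


def _fan_split_h(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s, d = _fan_split_w(x.T)
    return s.T, d.T


def _fan_merge_h(s: np.ndarray, d: np.ndarray) -> np.ndarray:
    return _fan_merge_w(s.T, d.T).T


# ----------------------------------------------------------- 1-D deep stage

def _split1d(x: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """(2,2)-lifting wavelet split along one axis (periodic)."""
    if x.shape[axis] % 2:
        raise ValueError("odd extent in directional split; depth too large")
    sl_e = [slice(None)] * 2
    sl_o = [slice(None)] * 2
    sl_e[axis] = slice(0, None, 2)
    sl_o[axis] = slice(1, None, 2)
    e, o = x[tuple(sl_e)], x[tuple(sl_o)]
    d = o - (e + np.roll(e, -1, axis)) / 2.0
    s = e + (d + np.roll(d, 1, axis)) / 4.0
    return s, d


def _merge1d(s: np.ndarray, d: np.ndarray, axis: int) -> np.ndarray:
    e = s - (d + np.roll(d, 1, axis)) / 4.0
    o = d + (e + np.roll(e, -1, axis)) / 2.0
    shape = list(s.shape)
    shape[axis] *= 2
    x = np.empty(shape, dtype=s.dtype)
    sl_e = [slice(None)] * 2
    sl_o = [slice(None)] * 2
    sl_e[axis] = slice(0, None, 2)
    sl_o[axis] = slice(1, None, 2)
    x[tuple(sl_e)] = e
    x[tuple(sl_o)] = o
    return x


# ------------------------------------------------------------------- trees

def dfb_decompose(x: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Decompose into ``2**n_levels`` directional bands (critically sampled)."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    bands = list(_fan_split_w(x))
    if n_levels == 1:
        return bands
    bands = [half for b in bands for half in _fan_split_h(b)]
    for _level in range(3, n_levels + 1):
        half = len(bands) // 2
        out: list[np.ndarray] = []
        for k, band in enumerate(bands):
            out.extend(_split1d(band, 0 if k < half else 1))
        bands = out
    return bands


def dfb_reconstruct(bands: list[np.ndarray], n_levels: int) -> np.ndarray:
    """Exact inverse of :func:`dfb_decompose`."""
    if len(bands) != 2**n_levels:
        raise ValueError(f"expected {2**n_levels} bands, got {len(bands)}")
    bands = [np.asarray(b, dtype=np.float64) for b in bands]
    for _level in range(n_levels, 2, -1):
        half = len(bands) // 4  # parent count in first tree half
        out = []
        for k in range(len(bands) // 2):
            out.append(_merge1d(bands[2 * k], bands[2 * k + 1], 0 if k < half else 1))
        bands = out
    if n_levels >= 2:
        bands = [_fan_merge_h(bands[2 * k], bands[2 * k + 1]) for k in range(len(bands) // 2)]
    return _fan_merge_w(bands[0], bands[1])


def dfb_band_shapes(shape: tuple[int, int], n_levels: int) -> list[tuple[int, int]]:
    """Band shapes produced by :func:`dfb_decompose` on an input of ``shape``."""
    h, w = shape
    n = 2**n_levels
    if n_levels == 1:
        return [(h, w // 2)] * 2
    first = (h // 2 ** (n_levels - 1), w // 2)
    second = (h // 2, w // 2 ** (n_levels - 1))
    return [first] * (n // 2) + [second] * (n // 2)
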