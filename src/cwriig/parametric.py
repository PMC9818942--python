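"""Sliding-window parametric maps and correlated weighting.

A parametric (CP) image replaces each sub-band coefficient by a local
distribution parameter: RiIG dispersion delta, Nakagami shape m, or NIG
steepness alpha, estimated on a sliding window (13 x 13 by default, the
span used for delta-mapping throughout) centered at the pixel.  The
correlated-weighted (CWCtr-/CWCrv-RiIG) image then replaces each pixel by
the windowed Pearson correlation between the coefficient image and its
parametric map, which is bounded in [-1, 1] by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.transform import resize

from . import transforms
from .images import normalize
from .keys import SubbandKey, default_contourlet_keys, default_curvelet_keys
from .models import nakagami_fit_batch, nig_fit_batch, riig_fit_batch
from .transforms import SubbandImage, select_subbands

__all__ = [
    "ParametricImage",
    "CorrelatedWeightedImage",
    "SubbandStack",
    "STACK_SIZE",
    "parameter_map",
    "multiplicative_weight",
    "correlated_weight",
    "build_stack",
]

STACK_SIZE = 224

_MODELS = ("riig", "nakagami", "nig")


@dataclass
class ParametricImage:
    """Per-pixel map of a locally fitted distribution parameter."""

    values: np.ndarray
    source_key: SubbandKey | None
    window: int
    stride: int
    model: str
    converged: np.ndarray  # bool mask, False where the moment fallback was used

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CorrelatedWeightedImage:
    """Windowed correlation of a sub-band with its parametric map, in [-1, 1]."""

    values: np.ndarray
    source_key: SubbandKey | None
    window: int


@dataclass
class SubbandStack:
    """Six 224 x 224 channels stacked in key order, the network input."""

    channels: np.ndarray  # (6, 224, 224)
    keys: tuple[SubbandKey, ...]
    label: str | None = None  # "benign" / "malignant"
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.channels.shape != (6, STACK_SIZE, STACK_SIZE):
            raise ValueError(f"stack must be (6, {STACK_SIZE}, {STACK_SIZE}), got {self.channels.shape}")


def _as_field(subband) -> tuple[np.ndarray, SubbandKey | None]:
    if isinstance(subband, SubbandImage):
        return np.asarray(subband.coeffs, dtype=np.float64), subband.key
    return np.asarray(subband, dtype=np.float64), None


def parameter_map(subband, model: str = "riig", window: int = 13, stride: int = 1) -> ParametricImage:
    """Map a sub-band to its local distribution parameter.

    Fits are computed on the absolute coefficient values (the models are
    nonnegative-envelope laws; contourlet coefficients are signed).
    Symmetric padding keeps the output extent equal to the input; with
    ``stride > 1`` only the stride grid is fitted and the gaps take the
    nearest computed value, which agrees exactly with stride 1 on the grid.
    """
    x, key = _as_field(subband)
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}, got {model!r}")
    if window % 2 == 0 or window < 5:
        raise ValueError(f"window must be odd and >= 5, got {window}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = x.shape
    if min(h, w) < window:
        raise ValueError(f"sub-band {x.shape} smaller than the {window}x{window} window")

    half = window // 2
    pad = np.pad(np.abs(x), half, mode="symmetric")
    view = np.lib.stride_tricks.sliding_window_view(pad, (window, window))
    gi = np.arange(0, h, stride)
    gj = np.arange(0, w, stride)
    wins = view[np.ix_(gi, gj)].reshape(gi.size * gj.size, window * window)

    if model == "riig":
        params, ok = riig_fit_batch(wins)
        mapped = params[:, 2]  # delta
    elif model == "nakagami":
        params, ok = nakagami_fit_batch(wins)
        mapped = params[:, 0]  # m
    else:
        params, ok = nig_fit_batch(wins)
        mapped = params[:, 0]  # alpha

    grid_vals = mapped.reshape(gi.size, gj.size)
    grid_ok = ok.reshape(gi.size, gj.size)
    if stride == 1:
        values, conv = grid_vals, grid_ok
    else:  # nearest computed grid point
        ii = np.clip(np.round(np.arange(h) / stride).astype(int), 0, gi.size - 1)
        jj = np.clip(np.round(np.arange(w) / stride).astype(int), 0, gj.size - 1)
        values = grid_vals[np.ix_(ii, jj)]
        conv = grid_ok[np.ix_(ii, jj)]
    return ParametricImage(values, key, window, stride, model, conv)


def multiplicative_weight(subband, pmap: ParametricImage | np.ndarray) -> np.ndarray:
    """|coefficients| * parameter map, min-max rescaled to [0, 1].

    The multiplicatively weighted (WCtr-/WCrv-RiIG) image, kept for
    comparison experiments against the correlated weighting.
    """
    x, _ = _as_field(subband)
    pv = pmap.values if isinstance(pmap, ParametricImage) else np.asarray(pmap, dtype=np.float64)
    if pv.shape != x.shape:
        raise ValueError(f"shape mismatch: sub-band {x.shape} vs map {pv.shape}")
    return normalize(np.abs(x) * pv)


def correlated_weight(subband, pmap: ParametricImage | np.ndarray, window: int = 13) -> CorrelatedWeightedImage:
    """Windowed Pearson correlation between sub-band and parametric map.

    Computed with reflective (symmetric) borders so the output extent
    equals the input.  Windows in which either field has (numerically)
    zero variance map to 0; the result is clipped to [-1, 1] to absorb
    last-bit rounding.
    """
    x, key = _as_field(subband)
    pv = pmap.values if isinstance(pmap, ParametricImage) else np.asarray(pmap, dtype=np.float64)
    if pv.shape != x.shape:
        raise ValueError(f"shape mismatch: sub-band {x.shape} vs map {pv.shape}")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")

    def _mean(a):
        return uniform_filter(a, size=window, mode="reflect")

    mx, my = _mean(x), _mean(pv)
    cov = _mean(x * pv) - mx * my
    vx = _mean(x * x) - mx * mx
    vy = _mean(pv * pv) - my * my
    # relative floor: cancellation noise on a constant window scales with m2
    fx = np.maximum(vx, 0.0) > 1e-12 * np.maximum(_mean(x * x), 1e-300)
    fy = np.maximum(vy, 0.0) > 1e-12 * np.maximum(_mean(pv * pv), 1e-300)
    valid = fx & fy
    denom = np.sqrt(np.maximum(vx, 1e-300) * np.maximum(vy, 1e-300))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(valid, cov / denom, 0.0)
    return CorrelatedWeightedImage(np.clip(rho, -1.0, 1.0), key, window)


def build_stack(
    image: np.ndarray,
    transform: str = "contourlet",
    model: str = "riig",
    keys: Sequence[SubbandKey] | None = None,
    window: int = 13,
    stride: int = 1,
    weighting: str = "correlated",
    label: str | None = None,
    source_id: str | None = None,
) -> SubbandStack:
    """B-mode image -> six correlated-weighted sub-band channels at 224 x 224.

    Pipeline: decompose -> select six sub-bands -> parameter map ->
    correlated (or multiplicative) weighting -> bilinear resize -> stack.

    The correlation is taken between the coefficient *magnitude* image and
    its parameter map -- the same domain the map was fitted on (the models
    are nonnegative-envelope laws); signed coefficients are symmetric
    about zero and would correlate to structureless noise.
    """
    if keys is None:
        keys = default_contourlet_keys() if transform == "contourlet" else default_curvelet_keys()
    keys = list(keys)
    if len(keys) != 6:
        raise ValueError(f"exactly 6 sub-band keys required, got {len(keys)}")
    if weighting not in ("correlated", "multiplicative"):
        raise ValueError(f"weighting must be 'correlated' or 'multiplicative', got {weighting!r}")
    dec = transforms.decompose(image, transform)
    subs = select_subbands(dec, keys)
    channels = np.empty((6, STACK_SIZE, STACK_SIZE))
    resolved = []
    for i, sub in enumerate(subs):
        pmap = parameter_map(sub, model, window=window, stride=stride)
        if weighting == "correlated":
            magnitude = SubbandImage(sub.key, np.abs(sub.coeffs))
            field = correlated_weight(magnitude, pmap, window=window).values
        else:
            field = multiplicative_weight(sub, pmap)
        channels[i] = resize(field, (STACK_SIZE, STACK_SIZE), order=1,
                             mode="reflect", anti_aliasing=False)
        resolved.append(sub.key)
    return SubbandStack(channels, tuple(resolved), label=label, source_id=source_id)
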