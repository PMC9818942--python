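"""Synthetic B-mode speckle images with elliptical lesions.

The generator emulates fully developed speckle: a dense complex
circular-Gaussian scatterer field is amplitude-modulated by a lesion mask,
blurred by a Gaussian point-spread function, envelope-detected and
log-compressed.  The background envelope before compression is Rayleigh by
construction.  The two classes differ the way benign and malignant breast
lesions do on B-mode: benign lesions are smooth, mildly hypoechoic ovals;
malignant lesions are markedly hypoechoic, eccentric, with irregular
(spiculated) margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .images import normalize
from .models import RiIGParams, riig_sample

__all__ = [
    "SpeckleConfig",
    "BENIGN_DEFAULT",
    "MALIGNANT_DEFAULT",
    "simulate_speckle",
    "lesion_mask",
    "make_dataset",
    "simulate_model_field",
]


@dataclass(frozen=True)
class SpeckleConfig:
    """Speckle-image generator settings.

    The background is a dense complex-Gaussian scatterer field (exact
    Rayleigh envelope).  The lesion modifies it the way breast lesions
    read on B-mode:

    * ``lesion_contrast`` scales scatterer amplitude (< 1: hypoechoic);
    * ``lesion_density`` sets scatterer counts per pixel inside the lesion
      -- hypocellular tissue (few scatterers per resolution cell) gives
      patchy, pre-Rayleigh texture that survives log compression;
    * ``boundary_irregularity`` perturbs the elliptical margin
      sinusoidally (spiculation);
    * ``rim_strength`` adds an echogenic capsule rim along the margin;
    * ``heterogeneity`` multiplies the interior by correlated lognormal
      texture (internal echo heterogeneity);
    * ``posterior`` scales the amplitude in the column beneath the lesion
      (> 1: posterior enhancement, < 1: acoustic shadowing).
    """

    size: int = 256
    scatterer_density: float = 4.0  # background scatterers per px^2
    lesion_density: float | None = None  # None: same texture as background
    psf_sigma: float = 1.5  # px
    lesion_axes: tuple[float, float] = (48.0, 36.0)  # semi-axes (rows, cols), px
    lesion_contrast: float = 0.5
    boundary_irregularity: float = 0.0
    boundary_lobes: int = 9  # angular frequency of the margin perturbation
    rim_strength: float = 0.0
    heterogeneity: float = 0.0  # log-sd of the interior texture field
    posterior: float = 1.0  # posterior column amplitude factor
    log_compression: float = 50.0  # dynamic-range gain; 0 disables
    class_label: str = "benign"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if self.scatterer_density <= 0:
            raise ValueError("scatterer_density must be > 0")
        if self.lesion_density is not None and self.lesion_density <= 0:
            raise ValueError("lesion_density must be > 0")
        if self.lesion_contrast <= 0:
            raise ValueError("lesion_contrast must be > 0")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if self.rim_strength < 0 or self.heterogeneity < 0 or self.posterior <= 0:
            raise ValueError("rim_strength/heterogeneity >= 0 and posterior > 0 required")
        if self.class_label not in ("benign", "malignant"):
            raise ValueError(f"class_label must be benign/malignant, got {self.class_label!r}")


#: Fibroadenoma-like: smooth oval, mildly hypoechoic, homogeneous interior,
#: thin echogenic capsule, posterior enhancement.
BENIGN_DEFAULT = SpeckleConfig(
    lesion_axes=(48.0, 36.0), lesion_contrast=0.55, lesion_density=2.0,
    boundary_irregularity=0.05, rim_strength=0.9, heterogeneity=0.0,
    posterior=1.5, class_label="benign",
)
#: Carcinoma-like: eccentric, markedly hypoechoic and hypocellular,
#: spiculated margin, heterogeneous interior, posterior shadowing.
MALIGNANT_DEFAULT = SpeckleConfig(
    lesion_axes=(52.0, 26.0), lesion_contrast=0.22, lesion_density=0.4,
    boundary_irregularity=0.45, rim_strength=0.1, heterogeneity=0.9,
    posterior=0.35, class_label="malignant",
)


def lesion_mask(config: SpeckleConfig, rng: np.random.Generator) -> np.ndarray:
    """Indicator of the lesion interior (1 inside, 0 outside)."""
    mask, _ = _lesion_geometry(config, rng)
    return mask


def _lesion_geometry(config: SpeckleConfig, rng: np.random.Generator):
    """Interior mask and rim-band mask of the (perturbed) ellipse."""
    n = config.size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = cx = (n - 1) / 2.0
    a, b = config.lesion_axes
    dy, dx = (yy - cy) / a, (xx - cx) / b
    radius = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    phase = rng.uniform(0, 2 * np.pi)
    bump = 1.0 + config.boundary_irregularity * np.sin(config.boundary_lobes * theta + phase)
    mask = (radius <= bump).astype(np.float64)
    rim = ((radius > 0.85 * bump) & (radius <= 1.05 * bump)).astype(np.float64)
    return mask, rim


def simulate_speckle(config: SpeckleConfig, return_envelope: bool = False):
    """Simulate one B-mode frame; reproducible from (config, seed).

    Returns the normalized [0, 1] image; with ``return_envelope=True`` also
    the pre-compression envelope (for statistical checks).
    """
    rng = np.random.default_rng(config.seed)
    n = config.size
    mask, rim = _lesion_geometry(config, rng)

    # scatterer-count texture inside the lesion only: the background stays an
    # exact complex-Gaussian field (Rayleigh envelope); hypocellular interiors
    # get per-pixel Poisson counts (compound representation), i.e. patchy
    # pre-Rayleigh texture
    amp = np.ones((n, n))
    les_density = config.lesion_density
    if les_density is not None and les_density != config.scatterer_density:
        counts = rng.poisson(les_density, size=(n, n))
        amp = np.where(mask > 0, np.sqrt(counts / les_density), amp)

    amp = amp * (1.0 + (config.lesion_contrast - 1.0) * mask)
    amp = amp * (1.0 + config.rim_strength * rim)
    if config.heterogeneity > 0:  # correlated lognormal internal echotexture
        field = gaussian_filter(rng.normal(size=(n, n)), 6.0)
        field *= config.heterogeneity / max(field.std(), 1e-12)
        amp = amp * np.where(mask > 0, np.exp(field - config.heterogeneity**2 / 2.0), 1.0)
    if config.posterior != 1.0:  # shadowing / enhancement beneath the lesion
        yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
        c = (n - 1) / 2.0
        lateral = np.clip(1.0 - np.abs(xx - c) / (config.lesion_axes[1] * 1.05), 0.0, 1.0)
        below = np.clip((yy - (c + config.lesion_axes[0] * 0.6)) / 30.0, 0.0, 1.0)
        amp = amp * (1.0 + (config.posterior - 1.0) * lateral * below)

    scat = (rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))) * (amp / np.sqrt(2.0))
    rf = gaussian_filter(scat.real, config.psf_sigma) + 1j * gaussian_filter(scat.imag, config.psf_sigma)
    envelope = np.abs(rf)
    if config.log_compression > 0:
        img = np.log1p(config.log_compression * envelope) / np.log1p(config.log_compression)
    else:
        img = envelope
    img = normalize(img)
    return (img, envelope) if return_envelope else img


@dataclass
class LabeledImage:
    image: np.ndarray
    label: str
    source_id: str
    seed: int


def make_dataset(
    n_per_class: int,
    benign_cfg: SpeckleConfig = BENIGN_DEFAULT,
    malignant_cfg: SpeckleConfig = MALIGNANT_DEFAULT,
    seed: int = 0,
) -> list[LabeledImage]:
    """Balanced two-class image set with unique per-image seeds and ids."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(2 * n_per_class) >> 1]  # keep < 2^31
    out = []
    for i in range(n_per_class):
        for j, cfg in enumerate((benign_cfg, malignant_cfg)):
            s = seeds[2 * i + j]
            c = replace(cfg, seed=s)
            out.append(LabeledImage(simulate_speckle(c), c.class_label,
                                    f"{c.class_label}_{i:04d}", s))
    return out


def simulate_model_field(law: str, params, size: int, seed: int) -> np.ndarray:
    """i.i.d. pixel field drawn from a named amplitude law (test fixture)."""
    rng = np.random.default_rng(seed)
    n = size * size
    if law == "riig":
        p = params if isinstance(params, RiIGParams) else RiIGParams(*params)
        vals = riig_sample(p, n, rng)
    elif law == "nakagami":
        from scipy import stats

        m, omega = params
        if m < 0.5 or omega <= 0:
            raise ValueError("need m >= 0.5 and omega > 0")
        vals = stats.nakagami.rvs(m, scale=np.sqrt(omega), size=n, random_state=rng)
    elif law == "rayleigh":
        sigma = float(params[0]) if np.ndim(params) else float(params)
        if sigma <= 0:
            raise ValueError("need sigma > 0")
        vals = sigma * np.hypot(rng.normal(size=n), rng.normal(size=n))
    else:
        raise ValueError(f"unknown law {law!r}")
    return vals.reshape(size, size)
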