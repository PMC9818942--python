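"""Speckle amplitude statistics: RiIG, Nakagami and NIG models.

The Rician inverse Gaussian (RiIG) law models an envelope whose Rice
variance is itself random, following an inverse Gaussian mixing density
with parameters (delta, gamma).  Its density is

    p(r) = sqrt(2/pi) * alpha^(3/2) * delta * exp(delta*gamma)
           * r * (delta^2 + r^2)^(-3/4)
           * K_{3/2}(alpha * sqrt(delta^2 + r^2)) * I_0(beta * r),  r >= 0,

with steepness alpha, skewness beta (|beta| < alpha), dispersion delta and
gamma = sqrt(alpha^2 - beta^2).  K_{3/2} has the elementary closed form
sqrt(pi/(2x)) e^(-x) (1 + 1/x), so the log-likelihood and its gradient are
fully closed-form; both the scalar fitter (L-BFGS-B) and the vectorized
many-window fitter used by parametric mapping share them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "RiIGParams",
    "NakagamiParams",
    "NIGParams",
    "FitResult",
    "log_k32",
    "riig_pdf",
    "riig_logpdf",
    "riig_cdf",
    "riig_sample",
    "riig_fit",
    "riig_fit_batch",
    "riig_loglik",
    "nakagami_pdf",
    "nakagami_fit",
    "nig_pdf",
    "nig_fit",
    "pp_plot_data",
    "PPModel",
]

_MIN_SAMPLES = 30


# ------------------------------------------------------------------ params

@dataclass(frozen=True)
class RiIGParams:
    """RiIG parameters (alpha, beta, delta); gamma is derived."""

    alpha: float
    beta: float
    delta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta) and np.isfinite(self.delta)):
            raise ValueError("RiIG parameters must be finite")
        if self.alpha <= abs(self.beta):
            raise ValueError(f"need alpha > |beta|, got alpha={self.alpha}, beta={self.beta}")
        if self.delta <= 0:
            raise ValueError(f"need delta > 0, got {self.delta}")

    @property
    def gamma(self) -> float:
        return float(np.sqrt(self.alpha**2 - self.beta**2))


@dataclass(frozen=True)
class NakagamiParams:
    m: float
    omega: float

    def __post_init__(self) -> None:
        if self.m < 0.5 or self.omega <= 0:
            raise ValueError(f"need m >= 0.5 and omega > 0, got {self}")


@dataclass(frozen=True)
class NIGParams:
    alpha: float
    beta: float
    delta: float
    mu: float

    def __post_init__(self) -> None:
        if self.alpha <= abs(self.beta):
            raise ValueError(f"need alpha > |beta|, got alpha={self.alpha}, beta={self.beta}")
        if self.delta <= 0:
            raise ValueError(f"need delta > 0, got {self.delta}")

    @property
    def gamma(self) -> float:
        return float(np.sqrt(self.alpha**2 - self.beta**2))


@dataclass
class FitResult:
    params: object
    loglik: float
    converged: bool
    n: int


# ------------------------------------------------------------------- RiIG

def log_k32(x: np.ndarray) -> np.ndarray:
    """log K_{3/2}(x) via its elementary closed form (stable for large x)."""
    x = np.asarray(x, dtype=np.float64)
    return 0.5 * (np.log(np.pi) - np.log(2.0) - np.log(x)) - x + np.log1p(1.0 / x)


def _log_i0(u: np.ndarray) -> np.ndarray:
    au = np.abs(u)
    return np.log(special.i0e(au)) + au


def riig_logpdf(r, p: RiIGParams) -> np.ndarray:
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("RiIG support is r >= 0")
    a, b, d = p.alpha, p.beta, p.delta
    with np.errstate(divide="ignore"):
        s = np.sqrt(d**2 + r**2)
        out = (
            0.5 * np.log(2.0 / np.pi)
            + 1.5 * np.log(a)
            + np.log(d)
            + d * p.gamma
            + np.log(r)
            - 0.75 * np.log(d**2 + r**2)
            + log_k32(a * s)
            + _log_i0(b * r)
        )
    return np.where(r > 0, out, -np.inf)


def riig_pdf(r, p: RiIGParams) -> np.ndarray:
    """RiIG density; returns 0 at r = 0."""
    out = np.exp(riig_logpdf(r, p))
    return out if np.ndim(r) else float(out)


def riig_cdf(r, p: RiIGParams, grid_size: int = 4096) -> np.ndarray:
    """Numerically integrated CDF, evaluated by interpolation on a fine grid."""
    r = np.atleast_1d(np.asarray(r, dtype=np.float64))
    rmax = max(float(r.max()), 8.0 * (p.delta / p.gamma + p.delta)) * 1.5 + 1.0
    grid = np.linspace(0.0, rmax, grid_size)
    pdf = riig_pdf(grid, p)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(grid))])
    cdf = np.clip(cdf / max(cdf[-1], 1.0), 0.0, 1.0) * min(cdf[-1], 1.0)
    return np.interp(r, grid, cdf)


def riig_sample(p: RiIGParams, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw n RiIG variates via the Rice-over-inverse-Gaussian mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam, mean = p.delta**2, p.delta / p.gamma
    z = stats.invgauss.rvs(mean / lam, scale=lam, size=n, random_state=rng)
    sd = np.sqrt(z)
    x = rng.normal(p.beta * z, sd)
    y = rng.normal(0.0, sd)
    return np.hypot(x, y)


def riig_loglik(samples: np.ndarray, p: RiIGParams) -> float:
    return float(np.sum(riig_logpdf(samples, p)))


def _nll_and_grad(u: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Negative log-likelihood and gradient in u = (log gamma, beta, log delta).

    Vectorized over leading window axes: u has shape (..., 3), r (..., n).
    """
    lg, b, ld = u[..., 0:1], u[..., 1:2], u[..., 2:3]
    g, d = np.exp(lg), np.exp(ld)
    a = np.sqrt(g**2 + b**2)
    s2 = d**2 + r**2
    s = np.sqrt(s2)
    x = a * s
    n = r.shape[-1]

    ll = (
        n * (0.5 * np.log(2.0 / np.pi) + 1.5 * np.log(a[..., 0]) + ld[..., 0] + (d * g)[..., 0])
        + np.sum(np.log(np.maximum(r, 1e-300)), axis=-1)
        - 0.75 * np.sum(np.log(s2), axis=-1)
        + np.sum(log_k32(x), axis=-1)
        + np.sum(_log_i0(b * r), axis=-1)
    )

    dlogk = -0.5 / x - 1.0 - 1.0 / (x**2 + x)
    common = 1.5 / a + dlogk * s
    br = b * r
    i_ratio = np.sign(br) * special.i1e(np.abs(br)) / special.i0e(np.abs(br))

    dg = np.sum(d + common * (g / a), axis=-1)
    db = np.sum(common * (b / a) + r * i_ratio, axis=-1)
    dd = np.sum(1.0 / d + g - 1.5 * d / s2 + dlogk * a * d / s, axis=-1)

    grad = np.stack([dg * g[..., 0], db, dd * d[..., 0]], axis=-1)
    return -ll, -grad


def _moment_init(r: np.ndarray) -> np.ndarray:
    """Moment-based (log gamma, beta, log delta) start, beta = 0."""
    m2 = np.mean(r**2, axis=-1)
    m4 = np.mean(r**4, axis=-1)
    a = np.maximum(m2 / 2.0, 1e-12)
    denom = m4 - 8.0 * a**2
    g2 = np.where(denom > 1e-12, 8.0 * a / np.maximum(denom, 1e-12), 1.0)
    g = np.sqrt(np.maximum(g2, 1e-4))
    d = np.maximum(a * g, 1e-8)
    zeros = np.zeros_like(g)
    return np.stack([np.log(g), zeros, np.log(d)], axis=-1)


def _check_samples(samples) -> np.ndarray:
    r = np.asarray(samples, dtype=np.float64).ravel()
    if r.size < _MIN_SAMPLES:
        raise ValueError(f"need at least {_MIN_SAMPLES} samples, got {r.size}")
    if np.ptp(r) == 0:
        raise ValueError("degenerate input: all samples equal")
    if np.any(r < 0):
        raise ValueError("samples must be nonnegative")
    return r


def _params_from_u(u: np.ndarray) -> RiIGParams:
    g, b, d = np.exp(u[0]), u[1], np.exp(u[2])
    return RiIGParams(float(np.sqrt(g**2 + b**2)), float(b), float(d))


def riig_fit(samples) -> FitResult:
    """Maximum-likelihood RiIG fit with moment initialization.

    Never raises on optimizer failure; returns ``converged=False`` with the
    moment estimates instead.  Degenerate (all-equal) input does raise.
    """
    r = _check_samples(samples)
    r = np.maximum(r, 1e-12)  # the likelihood has a log r term
    u0 = _moment_init(r)
    # The likelihood is exactly even in beta, so beta = 0 is always a
    # stationary point; a second start with beta > 0 lets skewed data
    # escape it (the sign of beta is not identifiable).
    starts = [u0, u0 + np.array([0.0, 0.5, 0.0])]
    best_u, best_ll, ok = u0, -float(_nll_and_grad(u0, r)[0]), False
    for s in starts:
        try:
            res = optimize.minimize(
                _nll_and_grad, s, args=(r,), jac=True, method="L-BFGS-B",
                bounds=[(-12.0, 8.0), (-500.0, 500.0), (-14.0, 7.0)],
            )
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            continue
        if res.success and np.all(np.isfinite(res.x)) and -float(res.fun) >= best_ll:
            best_u, best_ll, ok = res.x, -float(res.fun), True
    return FitResult(_params_from_u(best_u), best_ll, ok, r.size)


def _sym_nll_grad(w: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Gradient of the symmetric (beta = 0) RiIG NLL in w = (log gamma, log delta).

    With beta = 0, alpha = gamma and the Bessel-I factor drops out, which
    makes the windowed delta-map fit several times cheaper.
    """
    g = np.exp(w[..., 0:1])
    d = np.exp(w[..., 1:2])
    s2_ = d**2 + r**2
    s = np.sqrt(s2_)
    x = g * s
    dlogk = -0.5 / x - 1.0 - 1.0 / (x**2 + x)
    common = 1.5 / g + dlogk * s
    dg = np.sum(d + common, axis=-1)
    dd = np.sum(1.0 / d + g - 1.5 * d / s2_ + dlogk * g * d / s, axis=-1)
    return -np.stack([dg * g[..., 0], dd * d[..., 0]], axis=-1)


def riig_fit_batch(windows: np.ndarray, n_iter: int = 80, lr: float = 0.15) -> tuple[np.ndarray, np.ndarray]:
    """Fit the symmetric RiIG sub-model per row of ``windows`` (nw, ns).

    Vectorized Adam ascent on (log gamma, log delta) with beta fixed at 0:
    envelope windows are near-symmetric, beta = 0 is a stationary point of
    the full likelihood anyway (it is even in beta), and delta is the
    mapped parameter.  Returns ``(params, converged)`` with params (nw, 3)
    columns (alpha, beta, delta); rows with no spread come back
    non-converged with the moment fallback.
    """
    r = np.asarray(windows, dtype=np.float64)
    r = np.maximum(r, 1e-12)
    ok = np.ptp(r, axis=-1) > 0
    u0 = _moment_init(r)
    w = u0[..., [0, 2]].copy()
    m = np.zeros_like(w)
    v = np.zeros_like(w)
    b1, b2, eps = 0.9, 0.999, 1e-8
    for t in range(1, n_iter + 1):
        grad = _sym_nll_grad(w, r)
        grad = np.where(np.isfinite(grad), grad, 0.0)
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad**2
        w = w - lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
        np.clip(w[..., 0], -12.0, 8.0, out=w[..., 0])
        np.clip(w[..., 1], -14.0, 7.0, out=w[..., 1])
    g, d = np.exp(w[..., 0]), np.exp(w[..., 1])
    params = np.stack([g, np.zeros_like(g), d], axis=-1)
    return params, ok


# --------------------------------------------------------------- Nakagami

def nakagami_pdf(r, p: NakagamiParams) -> np.ndarray:
    out = stats.nakagami.pdf(np.asarray(r, dtype=np.float64), p.m, scale=np.sqrt(p.omega))
    return out if np.ndim(r) else float(out)


def nakagami_fit(samples) -> FitResult:
    """Moment (inverse normalized variance) Nakagami estimator.

    m = E[r^2]^2 / Var(r^2), omega = E[r^2]; m is clamped to the valid
    range m >= 1/2.
    """
    r = _check_samples(samples)
    i2 = r**2
    omega = float(np.mean(i2))
    var = float(np.var(i2))
    m = omega**2 / var if var > 0 else 0.5
    clamped = m < 0.5
    p = NakagamiParams(max(m, 0.5), omega)
    ll = float(np.sum(stats.nakagami.logpdf(np.maximum(r, 1e-12), p.m, scale=np.sqrt(p.omega))))
    return FitResult(p, ll, not clamped, r.size)


def nakagami_fit_batch(windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized moment Nakagami fit per row; returns ((nw, 2) [m, omega], ok)."""
    r = np.asarray(windows, dtype=np.float64)
    i2 = r**2
    omega = np.mean(i2, axis=-1)
    var = np.var(i2, axis=-1)
    ok = var > 0
    m = np.where(ok, omega**2 / np.maximum(var, 1e-300), 0.5)
    return np.stack([np.maximum(m, 0.5), np.maximum(omega, 1e-300)], axis=-1), ok


# -------------------------------------------------------------------- NIG

def _nig_frozen(p: NIGParams):
    return stats.norminvgauss(p.alpha * p.delta, p.beta * p.delta, loc=p.mu, scale=p.delta)


def nig_pdf(x, p: NIGParams) -> np.ndarray:
    out = _nig_frozen(p).pdf(np.asarray(x, dtype=np.float64))
    return out if np.ndim(x) else float(out)


def nig_fit(samples) -> FitResult:
    """NIG maximum-likelihood fit (scipy backend, moment-guided start)."""
    r = np.asarray(samples, dtype=np.float64).ravel()
    if r.size < _MIN_SAMPLES:
        raise ValueError(f"need at least {_MIN_SAMPLES} samples, got {r.size}")
    if np.ptp(r) == 0:
        raise ValueError("degenerate input: all samples equal")
    sd = float(np.std(r))
    try:
        a, b, loc, scale = stats.norminvgauss.fit(
            r, 2.0, 0.0, loc=float(np.mean(r)), scale=sd
        )
        p = NIGParams(a / scale, b / scale, scale, loc)
        ll = float(np.sum(stats.norminvgauss.logpdf(r, a, b, loc=loc, scale=scale)))
        return FitResult(p, ll, True, r.size)
    except (ValueError, RuntimeError):
        p = NIGParams(2.0 / sd, 0.0, sd, float(np.mean(r)))
        ll = float(np.sum(_nig_frozen(p).logpdf(r)))
        return FitResult(p, ll, False, r.size)


def nig_fit_batch(windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized symmetric-NIG moment fit per row; returns ((nw, 4), ok).

    Columns are (alpha, beta=0, delta, mu).  With beta = 0 the NIG moments
    give delta/gamma = Var and excess kurtosis 3/(delta*gamma); solving the
    two equations yields the estimator used for the per-window alpha map.
    """
    r = np.asarray(windows, dtype=np.float64)
    mu = np.mean(r, axis=-1)
    var = np.maximum(np.var(r, axis=-1), 1e-300)
    m4 = np.mean((r - mu[..., None]) ** 4, axis=-1)
    ok = var > 1e-290
    exk = np.maximum(m4 / var**2 - 3.0, 0.3)
    dg = 3.0 / exk  # delta * gamma
    g = np.sqrt(np.maximum(dg / var, 1e-12))  # gamma = sqrt(dg / Var)
    d = dg / g
    alpha = g  # beta = 0 -> alpha = gamma
    return np.stack([alpha, np.zeros_like(alpha), d, mu], axis=-1), ok


# ---------------------------------------------------------------- pp-plot

@dataclass
class PPModel:
    """Percentile-percentile pairs for one model plus deviation summary."""

    name: str
    points: np.ndarray  # (n, 2): empirical level vs model CDF
    mad: float  # mean absolute deviation from the diagonal


def pp_plot_data(samples, model_cdfs: Sequence[tuple[str, Callable]]) -> list[PPModel]:
    """pp-plot pairs (empirical quantile level vs model CDF) per model.

    ``model_cdfs`` is a sequence of (name, cdf callable).  Deviation of the
    point cloud from the diagonal summarizes goodness of fit.
    """
    r = np.sort(np.asarray(samples, dtype=np.float64).ravel())
    if r.size < 100:
        raise ValueError("need at least 100 samples for a pp-plot")
    emp = (np.arange(1, r.size + 1) - 0.5) / r.size
    out = []
    for name, cdf in model_cdfs:
        model = np.clip(np.asarray(cdf(r), dtype=np.float64), 0.0, 1.0)
        out.append(PPModel(name, np.column_stack([emp, model]), float(np.mean(np.abs(model - emp)))))
    return out
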