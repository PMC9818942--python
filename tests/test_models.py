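"""RiIG / Nakagami / NIG densities, samplers, fitters and pp-plots."""

import numpy as np
import pytest
from scipy import integrate, special, stats

from cwriig.models import (
    NakagamiParams,
    NIGParams,
    RiIGParams,
    log_k32,
    nakagami_fit,
    nakagami_pdf,
    nig_fit,
    nig_pdf,
    pp_plot_data,
    riig_cdf,
    riig_fit,
    riig_fit_batch,
    riig_loglik,
    riig_pdf,
    riig_sample,
)

GRID = [
    RiIGParams(a, b, d)
    for a in (1.0, 2.0, 4.0)
    for b in (-1.0, 0.0, 1.0)
    if abs(b) < a
    for d in (0.5, 1.0, 2.0)
]


class TestRiIGDensity:
    def test_zero_at_origin(self, riig_params):
        assert riig_pdf(0.0, riig_params) == 0.0

    @pytest.mark.parametrize("p", GRID, ids=lambda p: f"a{p.alpha}b{p.beta}d{p.delta}")
    def test_integrates_to_one(self, p):
        val, _ = integrate.quad(lambda r: riig_pdf(r, p), 0, np.inf, limit=200)
        assert abs(val - 1.0) < 1e-4

    def test_k32_matches_closed_form(self):
        x = np.logspace(-3, np.log10(50), 500)
        closed = np.sqrt(np.pi / (2 * x)) * np.exp(-x) * (1 + 1 / x)
        assert np.abs(np.exp(log_k32(x)) / closed - 1).max() < 1e-10
        # and agrees with the generic Bessel backend
        assert np.abs(np.exp(log_k32(x)) / special.kv(1.5, x) - 1).max() < 1e-10

    def test_even_in_beta_sign(self):
        r = np.linspace(0.01, 10, 50)
        assert np.array_equal(
            riig_pdf(r, RiIGParams(2, 1, 1)), riig_pdf(r, RiIGParams(2, -1, 1))
        )

    def test_mode_shifts_right_with_beta(self):
        r = np.linspace(1e-3, 20, 20000)
        modes = [r[np.argmax(riig_pdf(r, RiIGParams(3.0, b, 1.0)))] for b in (0.0, 1.0, 2.0)]
        assert modes[0] < modes[1] < modes[2]

    def test_steeper_with_alpha(self):
        # larger alpha concentrates the density: peak value grows
        r = np.linspace(1e-3, 20, 20000)
        peaks = [riig_pdf(r, RiIGParams(a, 0.0, 1.0)).max() for a in (1.0, 2.0, 4.0)]
        assert peaks[0] < peaks[1] < peaks[2]

    def test_stable_at_large_alpha_delta(self):
        p = RiIGParams(500.0, 0.0, 1.0)
        v = riig_pdf(np.linspace(0.01, 5, 100), p)
        assert np.all(np.isfinite(v))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            RiIGParams(1.0, 1.5, 1.0)  # |beta| >= alpha
        with pytest.raises(ValueError):
            RiIGParams(1.0, 0.0, -1.0)
        with pytest.raises(ValueError):
            riig_pdf(-0.1, RiIGParams(2, 0, 1))


class TestRiIGSampler:
    def test_ks_against_numeric_cdf(self, riig_params):
        s = riig_sample(riig_params, 10000, seed=1)
        res = stats.kstest(s, lambda q: riig_cdf(q, riig_params))
        assert res.pvalue > 0.01

    def test_deterministic_given_seed(self, riig_params):
        assert np.array_equal(riig_sample(riig_params, 100, 5), riig_sample(riig_params, 100, 5))

    def test_rejects_empty(self, riig_params):
        with pytest.raises(ValueError):
            riig_sample(riig_params, 0, 1)


class TestRiIGFit:
    def test_delta_recovery_median_under_10pct(self):
        errs = [
            abs(riig_fit(riig_sample(RiIGParams(2, 0, 1), 5000, seed + 7)).params.delta - 1.0)
            for seed in range(5)
        ]
        assert np.median(errs) < 0.10

    def test_fitted_loglik_beats_truth(self, riig_params):
        s = riig_sample(riig_params, 2000, 11)
        fit = riig_fit(s)
        assert fit.loglik >= riig_loglik(s, riig_params) - 1e-6

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError, match="degenerate|all samples equal"):
            riig_fit(np.ones(100))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least"):
            riig_fit(np.arange(10, dtype=float))

    def test_batch_fitter_matches_scalar_path(self):
        # the likelihood has a flat alpha-delta ridge at window-sized n, so
        # compare achieved log-likelihoods, not raw parameter values
        wins = np.stack([riig_sample(RiIGParams(2, 0, 1), 169, 50 + i) for i in range(8)])
        batch, ok = riig_fit_batch(wins)
        assert ok.all()
        for row, params in zip(wins, batch):
            scalar = riig_fit(row)
            ll_batch = riig_loglik(row, RiIGParams(*params))
            assert ll_batch >= scalar.loglik - 2.0
            assert abs(params[2] - scalar.params.delta) / scalar.params.delta < 0.10


class TestNakagami:
    def test_rayleigh_gives_m_one(self):
        r_gen = np.random.default_rng(77)
        r = np.hypot(r_gen.normal(size=10000), r_gen.normal(size=10000))
        fit = nakagami_fit(r)
        assert abs(fit.params.m - 1.0) < 0.05

    def test_pdf_integrates_to_one(self):
        p = NakagamiParams(1.3, 2.0)
        val, _ = integrate.quad(lambda r: nakagami_pdf(r, p), 0, np.inf)
        assert abs(val - 1.0) < 1e-6

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            nakagami_fit(np.full(50, 3.0))


class TestNIG:
    def test_pdf_integrates_to_one(self):
        p = NIGParams(2.0, 0.0, 1.0, 0.0)
        val, _ = integrate.quad(lambda x: nig_pdf(x, p), -np.inf, np.inf)
        assert abs(val - 1.0) < 1e-4

    def test_symmetric_data_gives_small_beta(self):
        s = np.random.default_rng(78).standard_t(df=8, size=4000)  # symmetric, heavyish tails
        fit = nig_fit(s)
        # beta CI ~ O(alpha / sqrt(n)); demand practical symmetry
        assert abs(fit.params.beta) < 0.5 * fit.params.alpha

    def test_invalid_skew_rejected(self):
        with pytest.raises(ValueError):
            NIGParams(1.0, 2.0, 1.0, 0.0)


class TestPPPlot:
    def test_self_consistency_on_diagonal(self, riig_params):
        s = riig_sample(riig_params, 10000, 21)
        fit = riig_fit(s)
        (m,) = pp_plot_data(s, [("riig", lambda q: riig_cdf(q, fit.params))])
        assert m.mad < 0.02
        assert m.points.shape == (10000, 2)
        assert m.points.min() >= 0 and m.points.max() <= 1

    def test_riig_beats_nakagami_on_riig_data(self, riig_params):
        s = riig_sample(riig_params, 8000, 22)
        fr = riig_fit(s)
        fn = nakagami_fit(s)
        models = pp_plot_data(
            s,
            [
                ("riig", lambda q: riig_cdf(q, fr.params)),
                ("nakagami", lambda q: stats.nakagami.cdf(q, fn.params.m, scale=np.sqrt(fn.params.omega))),
            ],
        )
        assert models[0].mad < models[1].mad

    def test_empty_model_list(self, riig_params):
        s = riig_sample(riig_params, 200, 23)
        assert pp_plot_data(s, []) == []
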