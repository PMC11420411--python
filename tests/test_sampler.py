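"""Schedule, Heun integrator, hijacking/regularization and NFE accounting."""

from decimal import Decimal, getcontext

import numpy as np
import pytest

from flowdenoise.denoiser import AnalyticDenoiser
from flowdenoise.metrics import psnr, roi_noise_sd
from flowdenoise.pfgmpp import GeometryConfig, INFINITE
from flowdenoise.sampler import (
    SamplerConfig,
    count_nfe,
    denoise_posterior,
    heun_step,
    make_schedule,
    sample_unconditional,
)


class CountingDenoiser:
    """Wraps another denoiser and counts evaluations."""

    def __init__(self, inner):
        self.inner = inner
        self.calls = 0

    def denoise(self, x, sigma):
        self.calls += 1
        return self.inner.denoise(x, sigma)


class TestSchedule:
    def test_endpoints(self):
        s = make_schedule(8, 0.002, 80.0, 7.0)
        assert s.t[0] == pytest.approx(80.0)
        assert s.t[7] == pytest.approx(0.002)
        assert s.t[8] == 0.0
        assert np.all(np.diff(s.t) < 0)

    def test_degenerate_single_step(self):
        s = make_schedule(1, 0.002, 80.0, 7.0)
        assert np.allclose(s.t, [80.0, 0.0])

    def test_closed_form_high_precision(self):
        # independent re-evaluation with 50-digit decimal arithmetic
        getcontext().prec = 50
        T, lo, hi, rho = 8, Decimal("0.002"), Decimal(80), Decimal(7)
        s = make_schedule(T, 0.002, 80.0, 7.0)
        inv = Decimal(1) / rho
        a, b = hi**inv, lo**inv
        for i in range(T):
            expect = (a + Decimal(i) / Decimal(T - 1) * (b - a)) ** rho
            assert s.t[i] == pytest.approx(float(expect), rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_schedule(0)
        with pytest.raises(ValueError):
            make_schedule(8, 80.0, 0.002)

    def test_prior_r_max_translation(self):
        s = make_schedule(8)
        assert s.prior_r_max(GeometryConfig(4, 16)) == pytest.approx(320.0)
        assert s.prior_r_max(GeometryConfig(4, INFINITE)) == pytest.approx(80.0)


class TestHeunStep:
    def test_zero_step(self, rng):
        geom = GeometryConfig(4, 8)
        model = AnalyticDenoiser([np.zeros(4)], geom)
        x = rng.standard_normal(4)
        out, nfe = heun_step(model, x, 1.0, 1.0)
        assert np.array_equal(out, x)
        assert nfe == 0

    def test_single_charge_euler_exact(self, rng):
        # field (x - y)/t is linear in x: one Euler step to t=0 lands on y
        geom = GeometryConfig(4, 8)
        y = rng.standard_normal(4)
        model = AnalyticDenoiser([y], geom)
        t = 0.9
        x = y + t * rng.standard_normal(4)
        out, nfe = heun_step(model, x, t, 0.0)
        assert np.allclose(out, y, atol=1e-12)
        assert nfe == 1

    def test_heun_exact_for_field_linear_in_t(self):
        # dx/dt = a + b t has quadratic solution; trapezoid integrates it exactly
        a, b = 0.7, -0.3

        class LinearField:
            def denoise(self, x, t):
                return x - t * (a + b * t)

        x0 = np.array([2.0])
        t0, t1 = 1.5, 0.5
        out, nfe = heun_step(LinearField(), x0, t0, t1)
        expect = x0 + a * (t1 - t0) + b / 2 * (t1**2 - t0**2)
        assert np.allclose(out, expect, rtol=1e-12)
        assert nfe == 2

    def test_t_cur_nonpositive_raises(self):
        with pytest.raises(ValueError):
            heun_step(AnalyticDenoiser([np.zeros(1)], GeometryConfig(1, 1)), np.zeros(1), 0.0, 0.0)


class TestUnconditional:
    def test_memorization_and_nfe(self, rng, toy_images_8):
        geom = GeometryConfig(64, 64)
        model = AnalyticDenoiser(toy_images_8, geom)
        cfg = SamplerConfig(schedule=make_schedule(32), geom=geom, mode="unconditional")
        dyn = max(im.max() for im in toy_images_8) - min(im.min() for im in toy_images_8)
        hits = 0
        n = 20
        for _ in range(n):
            res = sample_unconditional(model, cfg, (8, 8), rng)
            assert res.nfe == 2 * 32 - 1
            best = min(np.max(np.abs(res.output - y)) for y in toy_images_8)
            hits += best < 0.01 * dyn
        assert hits >= int(0.9 * n)

    def test_fixed_seed_identical(self, toy_images_8):
        geom = GeometryConfig(64, 64)
        model = AnalyticDenoiser(toy_images_8, geom)
        cfg = SamplerConfig(schedule=make_schedule(8), geom=geom, mode="unconditional")
        a = sample_unconditional(model, cfg, (8, 8), np.random.default_rng(3)).output
        b = sample_unconditional(model, cfg, (8, 8), np.random.default_rng(3)).output
        assert np.array_equal(a, b)

    def test_wrong_mode_raises(self, toy_images_8):
        geom = GeometryConfig(64, 64)
        cfg = SamplerConfig(schedule=make_schedule(8), geom=geom, mode="posterior")
        with pytest.raises(ValueError):
            sample_unconditional(AnalyticDenoiser(toy_images_8, geom), cfg, (8, 8),
                                 np.random.default_rng(0))


class TestPosterior:
    def test_w_zero_is_identity(self, rng, toy_images_8):
        geom = GeometryConfig(64, 64)
        model = AnalyticDenoiser(toy_images_8, geom)
        c = toy_images_8[0] + 0.2 * rng.standard_normal((8, 8))
        for tau in (0, 7):
            cfg = SamplerConfig(schedule=make_schedule(8), geom=geom, tau=tau, w=0.0)
            out = denoise_posterior(model, c, cfg).output
            assert np.array_equal(out, c)

    def test_single_step_equals_euler(self, rng, toy_images_8):
        geom = GeometryConfig(64, 64)
        model = AnalyticDenoiser(toy_images_8, geom)
        c = toy_images_8[1] + 0.2 * rng.standard_normal((8, 8))
        sched = make_schedule(8)
        cfg = SamplerConfig(schedule=sched, geom=geom, tau=7, w=1.0, mode="posterior")
        res = denoise_posterior(model, c, cfg)
        euler, _ = heun_step(model, c, sched.t[7], 0.0)
        assert np.allclose(res.output, euler)
        assert res.nfe == 1

    def test_single_charge_closed_form(self, rng):
        # output = w*y + (1-w)*c for the single-charge linear field
        geom = GeometryConfig(16, 32)
        y = rng.standard_normal((4, 4))
        model = AnalyticDenoiser([y], geom)
        c = rng.standard_normal((4, 4))
        for w in (0.0, 0.3, 0.5, 1.0):
            cfg = SamplerConfig(schedule=make_schedule(8), geom=geom, tau=7, w=w)
            out = denoise_posterior(model, c, cfg).output
            assert np.allclose(out, w * y + (1 - w) * c, atol=1e-6)

    def test_determinism(self, rng, toy_images_8):
        geom = GeometryConfig(64, 64)
        model = AnalyticDenoiser(toy_images_8, geom)
        c = toy_images_8[0] + 0.1 * rng.standard_normal((8, 8))
        cfg = SamplerConfig(schedule=make_schedule(8), geom=geom, tau=4, w=0.6)
        assert np.array_equal(
            denoise_posterior(model, c, cfg).output,
            denoise_posterior(model, c, cfg).output,
        )

    def test_regularize_only_needs_rng(self, toy_images_8):
        geom = GeometryConfig(64, 64)
        model = AnalyticDenoiser(toy_images_8, geom)
        cfg = SamplerConfig(schedule=make_schedule(8), geom=geom, mode="regularize_only")
        with pytest.raises(ValueError):
            denoise_posterior(model, toy_images_8[0], cfg)

    def test_shape_mismatch_raises(self, toy_images_8):
        geom = GeometryConfig(64, 64)
        model = AnalyticDenoiser(toy_images_8, geom)
        cfg = SamplerConfig(schedule=make_schedule(8), geom=geom)
        with pytest.raises(ValueError):
            denoise_posterior(model, np.zeros((4, 4)), cfg)


class TestAblationContract:
    """Qualitative behavior of the three sampling modes on synthetic pairs."""

    @pytest.fixture()
    def setup(self, rng):
        from flowdenoise.synthetic_ct import (
            DegradationConfig, default_head_spec, make_paired_eval_set,
        )
        spec = default_head_spec(16)
        clean, noisy = make_paired_eval_set(
            4, spec, DegradationConfig(noise_sd=60.0), seed=11
        )
        norm = lambda im: (im + 450.0) / 550.0
        clean = [norm(im) for im in clean]
        noisy = [norm(im) for im in noisy]
        geom = GeometryConfig(256, 128)
        return clean, noisy, AnalyticDenoiser(clean, geom), geom

    def test_posterior_improves_over_condition(self, setup):
        clean, noisy, model, geom = setup
        cfg = SamplerConfig(schedule=make_schedule(8), geom=geom, tau=7, w=0.5)
        dyn = max(im.max() for im in clean) - min(im.min() for im in clean)
        for y, c in zip(clean, noisy):
            out = denoise_posterior(model, c, cfg).output
            assert psnr(out, y, dyn) > psnr(c, y, dyn)

    def test_regularize_only_tracks_condition(self, setup, rng):
        clean, noisy, model, geom = setup
        cfg = SamplerConfig(
            schedule=make_schedule(8), geom=geom, w=0.5, mode="regularize_only"
        )
        c = noisy[0]
        prior = rng.standard_normal(c.shape)
        out = denoise_posterior(model, c, cfg, rng=np.random.default_rng(2)).output
        corr_c = np.corrcoef(out.ravel(), c.ravel())[0, 1]
        corr_prior = np.corrcoef(out.ravel(), prior.ravel())[0, 1]
        assert corr_c > 0.95
        assert corr_c > abs(corr_prior)

    def test_hijack_only_stronger_noise_reduction(self, setup):
        clean, noisy, model, geom = setup
        roi = (6, 10, 6, 10)  # inside the flat brain region
        sched = make_schedule(8)
        post = SamplerConfig(schedule=sched, geom=geom, tau=7, w=0.5, mode="posterior")
        hijack = SamplerConfig(schedule=sched, geom=geom, tau=7, w=1.0, mode="hijack_only")
        sd_post = np.mean(
            [roi_noise_sd(denoise_posterior(model, c, post).output, roi) for c in noisy]
        )
        sd_hijack = np.mean(
            [roi_noise_sd(denoise_posterior(model, c, hijack).output, roi) for c in noisy]
        )
        assert sd_hijack < sd_post


class TestNFE:
    @pytest.mark.parametrize("T,tau,expected", [(8, 7, 1), (8, 0, 15), (4, 1, 5), (1, 0, 1)])
    def test_count_nfe_posterior(self, T, tau, expected):
        geom = GeometryConfig(64, 64)
        cfg = SamplerConfig(schedule=make_schedule(T), geom=geom, tau=tau)
        assert count_nfe(cfg) == expected

    @pytest.mark.parametrize("T", [1, 2, 4, 8])
    @pytest.mark.parametrize("tau_frac", [0.0, 0.5, 1.0])
    def test_measured_calls_match_count(self, T, tau_frac, toy_images_8, rng):
        geom = GeometryConfig(64, 64)
        tau = min(T - 1, int(tau_frac * T))
        cfg = SamplerConfig(schedule=make_schedule(T), geom=geom, tau=tau)
        model = CountingDenoiser(AnalyticDenoiser(toy_images_8, geom))
        c = toy_images_8[0] + 0.1 * rng.standard_normal((8, 8))
        res = denoise_posterior(model, c, cfg)
        assert model.calls == res.nfe == count_nfe(cfg)

    def test_unconditional_t1(self, toy_images_8):
        geom = GeometryConfig(64, 64)
        cfg = SamplerConfig(schedule=make_schedule(1), geom=geom, mode="unconditional")
        model = CountingDenoiser(AnalyticDenoiser(toy_images_8, geom))
        res = sample_unconditional(model, cfg, (8, 8), np.random.default_rng(0))
        assert model.calls == res.nfe == count_nfe(cfg) == 1


class TestEDMReduction:
    def test_trajectories_agree(self, rng, toy_images_8):
        # D = 1e6 with translated r vs the infinite branch, same analytic denoiser
        big = GeometryConfig(64, 10**6)
        inf = GeometryConfig(64, INFINITE)
        c = toy_images_8[0] + 0.15 * rng.standard_normal((8, 8))
        sched = make_schedule(8)
        for tau in (0, 7):
            res_big = denoise_posterior(
                AnalyticDenoiser(toy_images_8, big), c,
                SamplerConfig(schedule=sched, geom=big, tau=tau, w=0.5),
                record_trajectory=True,
            )
            res_inf = denoise_posterior(
                AnalyticDenoiser(toy_images_8, inf), c,
                SamplerConfig(schedule=sched, geom=inf, tau=tau, w=0.5),
                record_trajectory=True,
            )
            for a, b in zip(res_big.trajectory, res_inf.trajectory):
                denom = max(np.linalg.norm(b), 1e-12)
                assert np.linalg.norm(a - b) / denom < 1e-4


class TestConfigValidation:
    def test_bad_tau(self):
        geom = GeometryConfig(4, 4)
        with pytest.raises(ValueError):
            SamplerConfig(schedule=make_schedule(4), geom=geom, tau=4)

    def test_bad_w(self):
        geom = GeometryConfig(4, 4)
        with pytest.raises(ValueError):
            SamplerConfig(schedule=make_schedule(4), geom=geom, w=1.5)

    def test_bad_mode(self):
        geom = GeometryConfig(4, 4)
        with pytest.raises(ValueError):
            SamplerConfig(schedule=make_schedule(4), geom=geom, mode="xyz")
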