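"""Map computation: ADC, relaxation conversion, gamma-variate fit, indices."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from radgbm.maps import (
    DynamicSeries,
    GammaVariateFit,
    compute_adc,
    correct_leakage,
    fit_gamma_variate,
    fit_gamma_variate_batch,
    gamma_variate,
    normalize_relative,
    perfusion_indices,
    signal_to_relaxation,
)
from radgbm.synth import DscParams, simulate_dsc_series


class TestComputeAdc:
    def test_equal_signals_give_zero(self):
        vol = np.full((4, 4, 1), 1000.0)
        adc, n_clamped = compute_adc(vol, vol, b=1000.0)
        assert np.all(adc == 0.0)
        assert n_clamped == 0

    def test_known_log_ratio(self):
        # ln(1000/135.335...) = 2 exactly when S_b = 1000*exp(-2)
        s0 = np.full((2, 2, 2), 1000.0)
        s1 = 1000.0 * np.exp(-2.0) * np.ones_like(s0)
        adc, _ = compute_adc(s0, s1, b=1000.0)
        assert np.allclose(adc, 2.0e-3, rtol=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        s0 = rng.uniform(500, 1500, size=1000)
        s1 = rng.uniform(100, 1400, size=1000)
        adc, n_clamped = compute_adc(s0, s1, b=1000.0)
        oracle = np.log(s0 / s1) / 1000.0
        clamped = oracle < 0
        assert n_clamped == clamped.sum()
        assert np.allclose(adc[~clamped], oracle[~clamped], rtol=0, atol=1e-15)
        assert np.all(adc[clamped] == 0.0)

    def test_scaling_invariance(self, rng):
        s0 = rng.uniform(500, 1500, size=50)
        s1 = rng.uniform(400, 1400, size=50)
        a1, _ = compute_adc(s0, s1)
        a2, _ = compute_adc(7.3 * s0, 7.3 * s1)
        assert np.allclose(a1, a2, atol=1e-15)

    def test_nonpositive_signal_raises(self):
        s = np.ones(5)
        bad = s.copy()
        bad[2] = 0.0
        with pytest.raises(ValueError, match="1 voxels"):
            compute_adc(bad, s)


class TestSignalToRelaxation:
    def test_flat_series_is_zero(self):
        series = DynamicSeries(np.full((20, 3, 3, 1), 100.0), tr=1.72, te=0.035)
        assert np.allclose(signal_to_relaxation(series), 0.0)

    def test_closed_form_drop(self):
        # S = S_base * exp(-0.35) with TE = 0.035 s -> dR2* = 10 1/s
        data = np.full((20, 2, 2, 1), 100.0)
        data[10:] = 100.0 * np.exp(-0.35)
        series = DynamicSeries(data, tr=1.72, te=0.035, baseline_window=slice(0, 5))
        out = signal_to_relaxation(series)
        assert np.allclose(out[10:], 10.0, rtol=1e-12)

    def test_roundtrip_from_simulator(self):
        params = {"k_amp": 8.0, "t0": 15.0, "alpha_g": 2.0, "beta_g": 2.0}
        series = simulate_dsc_series(params, DscParams(), noise_sd=0.0)
        curve = signal_to_relaxation(series)
        expected = gamma_variate(series.times, 8.0, 15.0, 2.0, 2.0)
        assert np.allclose(curve, expected, atol=1e-9)

    def test_scale_equivariance(self):
        params = {"k_amp": 8.0, "t0": 15.0, "alpha_g": 2.0, "beta_g": 2.0}
        series = simulate_dsc_series(params, DscParams(), noise_sd=0.0)
        scaled = DynamicSeries(3.7 * series.data, series.tr, series.te,
                               series.baseline_window)
        assert np.allclose(signal_to_relaxation(series),
                           signal_to_relaxation(scaled), atol=1e-10)


class TestGammaVariateFit:
    def test_noiseless_recovery_canonical(self):
        t = np.linspace(0.0, 12.0, 60)
        curve = gamma_variate(t, 1.0, 0.0, 2.0, 1.0)
        fit = fit_gamma_variate(curve, t)
        assert fit.converged
        for got, true in ((fit.k_amp, 1.0), (fit.alpha_g, 2.0), (fit.beta_g, 1.0)):
            assert abs(got - true) / true < 1e-6
        assert abs(fit.t0) < 1e-6

    def test_noiseless_recovery_dsc_geometry(self):
        t = np.arange(50) * 1.72
        curve = gamma_variate(t, 5.0, 15.0, 2.0, 2.5)
        fit = fit_gamma_variate(curve, t)
        assert fit.converged
        for got, true in ((fit.k_amp, 5.0), (fit.t0, 15.0),
                          (fit.alpha_g, 2.0), (fit.beta_g, 2.5)):
            assert abs(got - true) / true < 1e-6

    def test_flat_curve_not_converged(self):
        fit = fit_gamma_variate(np.zeros(50), np.arange(50) * 1.72)
        assert not fit.converged

    def test_noise_robustness_median_error(self, rng):
        # 1% of peak additive noise: each parameter within 5% (median of 100)
        t = np.linspace(0.0, 15.0, 80)
        truth = dict(k_amp=1.0, t0=2.0, alpha_g=2.0, beta_g=1.0)
        c0 = gamma_variate(t, **truth)
        curves = c0 + rng.normal(0.0, 0.01 * c0.max(), size=(100, t.size))
        res = fit_gamma_variate_batch(curves, t)
        assert res["converged"].all()
        for name, true in truth.items():
            med = np.median(np.abs(res[name] - true) / true)
            assert med < 0.05, f"{name} median rel err {med:.3f}"

    def test_agrees_with_scipy_least_squares(self, rng):
        """Independent optimizer cross-check on one noisy curve."""
        t = np.arange(50) * 1.72
        c0 = gamma_variate(t, 5.0, 15.0, 2.0, 2.5)
        y = c0 + rng.normal(0.0, 0.005 * c0.max(), size=t.size)
        fit = fit_gamma_variate(y, t)
        from radgbm.maps import _fit_window

        w = _fit_window(y[None, :], 0.2)[0]

        def resid(p):
            return gamma_variate(t[w], *p) - y[w]

        ref = least_squares(resid, x0=[4.0, 14.0, 1.8, 2.8], method="lm")
        assert np.allclose(
            [fit.k_amp, fit.t0, fit.alpha_g, fit.beta_g], ref.x, rtol=1e-3
        )


class TestCorrectLeakage:
    def _first_pass(self):
        t = np.arange(50) * 1.72
        return t, gamma_variate(t, 8.0, 15.0, 2.0, 2.0)

    def test_no_leak_identity(self):
        t, c = self._first_pass()
        corrected, k2 = correct_leakage(c, c, t)
        assert abs(k2) < 1e-8
        assert np.allclose(corrected, c, atol=1e-8)

    def test_planted_k2_recovery(self):
        t, ref = self._first_pass()
        from radgbm.maps import _cumtrapz

        leaky = 1.3 * ref - 0.05 * _cumtrapz(ref, t)
        corrected, k2 = correct_leakage(leaky, ref, t)
        assert abs(k2 - 0.05) < 1e-6
        assert np.allclose(corrected, 1.3 * ref, atol=1e-6)

    def test_leaky_tail_restored_to_baseline(self):
        dsc = DscParams()
        params = {"k_amp": 8.0, "t0": 15.0, "alpha_g": 2.0, "beta_g": 2.0}
        series = simulate_dsc_series(params, dsc, leakage_k2=0.05, noise_sd=0.0)
        curve = signal_to_relaxation(series)
        peak = curve.max()
        assert abs(curve[-1]) > 0.05 * peak  # leak: tail off baseline
        ref = gamma_variate(series.times, 8.0, 15.0, 2.0, 2.0)
        corrected, _ = correct_leakage(curve, ref, series.times)
        assert abs(corrected[-1]) < 0.05 * peak

    def test_constant_reference_raises(self):
        t, c = self._first_pass()
        with pytest.raises(ValueError, match="constant"):
            correct_leakage(c, np.ones_like(c), t)


class TestPerfusionIndices:
    def test_closed_form_case(self):
        fit = GammaVariateFit(1.0, 0.0, 2.0, 1.0, 0.0, True)
        cbv, cbf, mtt, ttp = perfusion_indices(fit)
        assert np.allclose([cbv, mtt, ttp, cbf], [2.0, 3.0, 2.0, 2.0 / 3.0], rtol=1e-12)

    def test_beta_scales_mtt_and_ttp(self):
        f1 = GammaVariateFit(1.0, 3.0, 2.0, 1.0, 0.0, True)
        f2 = GammaVariateFit(1.0, 3.0, 2.0, 2.0, 0.0, True)
        _, _, mtt1, ttp1 = perfusion_indices(f1)
        _, _, mtt2, ttp2 = perfusion_indices(f2)
        assert mtt2 == pytest.approx(2 * mtt1)
        assert (ttp2 - 3.0) == pytest.approx(2 * (ttp1 - 3.0))

    def test_cbv_matches_quadrature(self):
        fit = GammaVariateFit(2.5, 4.0, 1.7, 2.2, 0.0, True)
        cbv, _, _, _ = perfusion_indices(fit)
        horizon = 10 * (fit.t0 + fit.alpha_g * fit.beta_g)
        t = np.linspace(0, horizon, 200001)
        numeric = np.trapezoid(
            gamma_variate(t, fit.k_amp, fit.t0, fit.alpha_g, fit.beta_g), t
        )
        assert abs(cbv - numeric) / numeric < 1e-3

    def test_nonconverged_gives_nan(self):
        fit = GammaVariateFit(0.0, 0.0, np.nan, np.nan, np.nan, False)
        assert all(np.isnan(v) for v in perfusion_indices(fit))


class TestNormalizeRelative:
    def test_constant_reference(self):
        m = np.arange(24, dtype=float).reshape(2, 3, 4) + 1
        mask = np.zeros_like(m, dtype=bool)
        mask[0, 0, :] = True
        m[mask] = 5.0
        out = normalize_relative(m, mask)
        assert np.allclose(out, m / 5.0)

    def test_reference_median_is_one(self, rng):
        m = rng.uniform(1, 10, size=(6, 6, 3))
        mask = rng.random((6, 6, 3)) < 0.4
        mask[0, 0, 0] = True
        out = normalize_relative(m, mask)
        assert np.median(out[mask]) == pytest.approx(1.0)

    def test_elementwise_oracle(self, rng):
        m = rng.uniform(1, 10, size=(5, 5, 2))
        mask = np.zeros_like(m, dtype=bool)
        mask[2, :, :] = True
        out = normalize_relative(m, mask)
        assert np.allclose(out, m / np.median(m[2]), atol=1e-14)

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_relative(np.ones((3, 3, 1)), np.zeros((3, 3, 1), dtype=bool))


class TestRoundTripPipeline:
    def test_simulate_fit_indices_roundtrip(self):
        """Noiseless chain: simulate -> dR2* -> fit -> indices, <=1e-4 relative."""
        from scipy.special import gamma as gamma_fn

        k, t0, a, b = 10.0, 15.0, 2.0, 2.2
        series = simulate_dsc_series(
            {"k_amp": k, "t0": t0, "alpha_g": a, "beta_g": b}, DscParams(), noise_sd=0.0
        )
        fit = fit_gamma_variate(signal_to_relaxation(series), series.times)
        cbv, cbf, mtt, ttp = perfusion_indices(fit)
        cbv_true = k * b ** (a + 1) * gamma_fn(a + 1)
        assert abs(cbv - cbv_true) / cbv_true < 1e-4
        assert abs(mtt - b * (a + 1)) / (b * (a + 1)) < 1e-4
        assert abs(ttp - (t0 + a * b)) / (t0 + a * b) < 1e-4

    def test_signal_scaling_leaves_indices_unchanged(self):
        params = {"k_amp": 10.0, "t0": 15.0, "alpha_g": 2.0, "beta_g": 2.2}
        series = simulate_dsc_series(params, DscParams(), noise_sd=0.0)
        scaled = DynamicSeries(5.0 * series.data, series.tr, series.te,
                               series.baseline_window)
        f1 = fit_gamma_variate(signal_to_relaxation(series), series.times)
        f2 = fit_gamma_variate(signal_to_relaxation(scaled), scaled.times)
        assert np.allclose(
            perfusion_indices(f1), perfusion_indices(f2), rtol=1e-8
        )
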