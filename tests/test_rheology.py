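"""Rheology analysis against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from condrheo.rheology import (
    ComplexModulusSeries,
    MaxwellFit,
    ModulusSpectrum,
    NonlinearResponseError,
    StressSeries,
    classify_response,
    crossover_frequencies,
    dynamic_viscosity,
    fit_maxwell,
    gk_complex_modulus,
    linear_regime_check,
    multitau_correlate,
    os_moduli,
)


def ou_process(n, tau, dt, rng, s=1.0):
    """Ornstein-Uhlenbeck samples with autocorrelation s^2 exp(-t/tau)."""
    a = math.exp(-dt / tau)
    b = s * math.sqrt(1 - a * a)
    x = np.empty(n)
    x[0] = s * rng.standard_normal()
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * rng.standard_normal()
    return x


class TestMultitau:
    def test_constant_series(self):
        lags, corr = multitau_correlate(np.full(2000, 3.0))
        np.testing.assert_allclose(corr, 9.0, rtol=1e-12)

    def test_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.0, 100000)
        lags, corr = multitau_correlate(x)
        assert corr[0] == pytest.approx(4.0, rel=0.03)
        assert np.all(np.abs(corr[1:]) < 0.15)

    def test_matches_brute_force_on_ou(self):
        """Within 2% of the direct O(N^2) autocorrelation at every shared lag."""
        rng = np.random.default_rng(1)
        tau = 100.0
        x = ou_process(30000, tau=tau, dt=1.0, rng=rng)
        lags, corr = multitau_correlate(x, lags_per_block=32)
        for lag, c in zip(lags.astype(int), corr):
            if lag > 1.5 * tau:  # beyond the resolvable decay both are noise
                continue
            ref = float(np.dot(x[: len(x) - lag], x[lag:]) / (len(x) - lag))
            assert c == pytest.approx(ref, rel=0.02)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            multitau_correlate(np.ones(10), lags_per_block=16)


class TestGreenKubo:
    def test_zero_stress_gives_zero(self):
        n = 1000
        z = np.zeros(n)
        s = StressSeries(np.arange(n) * 0.1, z, z, z, z, z, z, volume=100.0, temperature=1.0)
        gk = gk_complex_modulus(s)
        np.testing.assert_allclose(gk.g, 0.0)

    def test_isotropic_identity(self):
        """With identical off-diagonal channels and normal differences equal
        to twice that signal, the 5-term estimator collapses to
        V/(kB T) <Sxy(0) Sxy(t)> — the identity that pins the 1/6 weight."""
        rng = np.random.default_rng(2)
        x = ou_process(20000, tau=20.0, dt=0.5, rng=rng)
        t = np.arange(len(x)) * 0.5
        v, temp = 50.0, 1.2
        s = StressSeries(t, x, x, x, 2 * x, 2 * x, 2 * x, volume=v, temperature=temp)
        gk = gk_complex_modulus(s)
        lags, c = multitau_correlate(x)
        cn = multitau_correlate(2 * x - (2 * x).mean())[1]
        expect = v / (5 * temp) * (3 * c + 0.5 * cn)
        np.testing.assert_allclose(gk.g, expect, rtol=1e-10)

    def test_exponential_autocorrelation_through_estimator(self):
        """Independent OU channels with known C e^{-t/tau}: the estimator
        returns V/(5kBT)(3 + 3/6 x 4) C(t) within statistical tolerance."""
        rng = np.random.default_rng(3)
        tau, dt, s2 = 30.0, 0.5, 1.0
        n = 60000
        off = [ou_process(n, tau, dt, rng) for _ in range(3)]
        nd = [2 * ou_process(n, tau, dt, rng) for _ in range(3)]
        t = np.arange(n) * dt
        v, temp = 10.0, 1.0
        s = StressSeries(t, *off, *nd, volume=v, temperature=temp)
        gk = gk_complex_modulus(s)
        sel = (gk.lag_times > 0) & (gk.lag_times < 2 * tau)
        expect = v / (5 * temp) * (3 + 0.5 * 4) * s2 * np.exp(-gk.lag_times[sel] / tau)
        np.testing.assert_allclose(gk.g[sel], expect, rtol=0.25, atol=0.3)

    def test_linearity_in_stress_squared(self):
        """Doubling every stress channel quadruples G*(t)."""
        rng = np.random.default_rng(4)
        ch = [ou_process(4000, 10.0, 0.5, rng) for _ in range(6)]
        t = np.arange(4000) * 0.5
        s1 = StressSeries(t, *ch, volume=1.0, temperature=1.0)
        s2 = StressSeries(t, *[2 * c for c in ch], volume=1.0, temperature=1.0)
        g1 = gk_complex_modulus(s1)
        g2 = gk_complex_modulus(s2)
        np.testing.assert_allclose(g2.g, 4.0 * g1.g, rtol=1e-12)

    def test_offdiag_fallback_flagged(self):
        rng = np.random.default_rng(5)
        x = ou_process(2000, 10.0, 0.5, rng)
        t = np.arange(2000) * 0.5
        s = StressSeries(t, x, x, x, None, None, None, volume=1.0, temperature=1.0)
        gk = gk_complex_modulus(s)
        assert gk.offdiag_only

    def test_sheared_series_rejected(self):
        t = np.arange(100) * 0.1
        z = np.zeros(100)
        s = StressSeries(t, z, z, z, z, z, z, 1.0, 1.0, strain=np.sin(t))
        with pytest.raises(ValueError):
            gk_complex_modulus(s)


class TestOsModuli:
    def test_constructed_signal_exact(self):
        w = 0.7
        t = np.arange(0, 12 * 2 * math.pi / w, 0.01)
        strain = 0.1 * np.sin(w * t)
        stress = 0.1 * (2.0 * np.sin(w * t) + 1.0 * np.cos(w * t))
        pt = os_moduli(t, strain, stress, w)
        assert pt.g_storage == pytest.approx(2.0, rel=1e-9)
        assert pt.g_loss == pytest.approx(1.0, rel=1e-9)
        assert pt.delta == pytest.approx(math.atan2(1, 2), rel=1e-9)
        assert pt.sigma0 == pytest.approx(0.1 * math.hypot(2, 1), rel=1e-9)

    def test_in_phase_stress_is_purely_elastic(self):
        w = 0.5
        t = np.arange(0, 10 * 2 * math.pi / w, 0.01)
        strain = 0.2 * np.sin(w * t)
        pt = os_moduli(t, strain, 5.0 * strain, w)
        assert pt.g_loss == pytest.approx(0.0, abs=1e-9)
        assert pt.g_storage == pytest.approx(5.0, rel=1e-9)

    def test_maxwell_ode_oracle(self):
        """A single-mode Maxwell element integrated by its constitutive ODE
        under sinusoidal strain reproduces the closed-form G'(w), G''(w)."""
        g1, tau = 4.0, 10.0
        gamma0 = 0.1
        for w in (0.03, 0.1, 0.5):
            t_end = 25 * 2 * math.pi / w

            def rhs(t, y):
                rate = gamma0 * w * math.cos(w * t)
                return g1 * rate - y[0] / tau

            sol = solve_ivp(rhs, (0, t_end), [0.0], max_step=0.02 * 2 * math.pi / w,
                            dense_output=True, rtol=1e-10, atol=1e-12)
            t = np.linspace(0.4 * t_end, t_end, 4000)
            stress = sol.sol(t)[0]
            strain = gamma0 * np.sin(w * t)
            pt = os_moduli(t - t[0] + 10 * 2 * math.pi / w,
                           strain, stress, w, discard_cycles=0)
            # phase reference differs; compare amplitude-derived moduli
            wt = w * tau
            gp_ref = g1 * wt**2 / (1 + wt**2)
            gpp_ref = g1 * wt / (1 + wt**2)
            assert pt.sigma0 / gamma0 == pytest.approx(math.hypot(gp_ref, gpp_ref), rel=0.01)

    def test_noisy_nonlinear_rejected(self):
        rng = np.random.default_rng(6)
        w = 0.5
        t = np.arange(0, 10 * 2 * math.pi / w, 0.01)
        strain = 0.1 * np.sin(w * t)
        stress = 0.001 * np.sin(w * t) + rng.normal(0, 1.0, len(t))
        with pytest.raises(NonlinearResponseError):
            os_moduli(t, strain, stress, w)


class TestLinearRegime:
    def test_ideal_linear_material_full_sweep(self):
        pts = [(g, 2.0, 1.0) for g in (0.01, 0.05, 0.1, 0.2, 0.5)]
        win = linear_regime_check(pts)
        assert win.ok and win.gamma_max == 0.5

    def test_cubic_nonlinearity_window(self):
        """G' grows as G0(1 + c gamma0^2): the window ends where the cubic
        term exceeds 10%."""
        c = 4.0
        gammas = [0.01, 0.05, 0.1, 0.15, 0.2, 0.3]
        pts = [(g, 2.0 * (1 + c * g * g), 1.0) for g in gammas]
        win = linear_regime_check(pts)
        # c g^2 * G'/ref crosses 0.1*max(G',G'')=0.2/2 -> g* = sqrt(0.1/4) ~ 0.158
        assert win.gamma_max == pytest.approx(0.15)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            linear_regime_check([(0.1, 1, 1), (0.2, 1, 1)])


class TestMaxwellFit:
    def test_single_mode_exact_recovery(self):
        t = np.geomspace(0.5, 2000, 120)
        g = 5.0 * np.exp(-t / 100.0)
        fit = fit_maxwell(ComplexModulusSeries(t, g), n_modes=1, plateau=False)
        assert fit.g_modes[0] == pytest.approx(5.0, rel=1e-6)
        assert fit.tau_modes[0] == pytest.approx(100.0, rel=1e-6)

    def test_single_mode_crossover_value(self):
        fit = MaxwellFit([5.0], [100.0])
        w = np.array([1.0 / 100.0])
        assert fit.storage(w)[0] == pytest.approx(2.5, rel=1e-12)
        assert fit.loss(w)[0] == pytest.approx(2.5, rel=1e-12)

    def test_two_modes_wide_separation(self):
        t = np.geomspace(0.02, 5000, 200)
        g = 3.0 * np.exp(-t / 2.0) + 1.0 * np.exp(-t / 200.0)
        fit = fit_maxwell(ComplexModulusSeries(t, g), n_modes=2, plateau=False)
        assert fit.g_modes[0] == pytest.approx(3.0, rel=0.02)
        assert fit.tau_modes[0] == pytest.approx(2.0, rel=0.02)
        assert fit.g_modes[1] == pytest.approx(1.0, rel=0.02)
        assert fit.tau_modes[1] == pytest.approx(200.0, rel=0.02)

    def test_mode_count_by_residual_plateau(self):
        t = np.geomspace(0.02, 5000, 200)
        g = 3.0 * np.exp(-t / 2.0) + 1.0 * np.exp(-t / 200.0)
        fit = fit_maxwell(ComplexModulusSeries(t, g))
        assert fit.n_modes == 2

    def test_frequency_domain_fit(self):
        w = np.geomspace(1e-4, 10, 80)
        truth = MaxwellFit([2.0], [50.0])
        spec = truth.spectrum(w)
        fit = fit_maxwell(spec, n_modes=1)
        assert fit.g_modes[0] == pytest.approx(2.0, rel=1e-6)
        assert fit.tau_modes[0] == pytest.approx(50.0, rel=1e-6)

    def test_gel_plateau_detected(self):
        t = np.geomspace(0.1, 1000, 100)
        g = 2.0 * np.exp(-t / 5.0) + 1.5
        fit = fit_maxwell(ComplexModulusSeries(t, g), n_modes=1, plateau="auto")
        assert fit.plateau == pytest.approx(1.5, rel=0.01)
        assert math.isinf(fit.eta_star)


class TestViscosity:
    def test_single_mode_analytic(self):
        assert dynamic_viscosity(MaxwellFit([3.0], [7.0])) == pytest.approx(21.0)

    def test_zero_modulus(self):
        t = np.linspace(0, 100, 500)
        assert dynamic_viscosity(ComplexModulusSeries(t, np.zeros_like(t))) == 0.0

    def test_quadrature_matches_mode_sum(self):
        """Numerically integrated two-mode G*(t) within 0.5% of sum G_i tau_i."""
        fit = MaxwellFit([3.0, 1.0], [2.0, 200.0])
        t = np.linspace(0, 2000.0, 200001)
        series = ComplexModulusSeries(t, fit.g_of_t(t))
        eta = dynamic_viscosity(series)
        assert eta == pytest.approx(fit.eta_star, rel=0.005)

    def test_gel_reports_infinite(self):
        t = np.linspace(0, 100, 500)
        g = 1.0 + np.exp(-t / 3.0)
        with pytest.warns(UserWarning):
            assert math.isinf(dynamic_viscosity(ComplexModulusSeries(t, g)))


class TestCrossoversAndClassification:
    def test_single_mode_single_crossover(self):
        fit = MaxwellFit([5.0], [100.0])
        spec = fit.spectrum(np.geomspace(1e-5, 1, 400))
        xs = crossover_frequencies(spec)
        assert len(xs) == 1
        assert xs[0].omega == pytest.approx(0.01, rel=0.01)
        assert xs[0].below == "loss" and xs[0].above == "storage"

    def test_crossover_matches_dense_grid(self):
        fit = MaxwellFit([2.0, 1.0], [1.0, 300.0])
        coarse = fit.spectrum(np.geomspace(1e-5, 10, 60))
        dense = fit.spectrum(np.geomspace(1e-5, 10, 20000))
        xs_c = crossover_frequencies(coarse)
        xs_d = crossover_frequencies(dense)
        assert len(xs_c) == len(xs_d)
        step = (10 / 1e-5) ** (1 / 59)
        for a, b in zip(xs_c, xs_d):
            assert a.omega / b.omega < step and b.omega / a.omega < step

    def test_two_sign_changes_found_in_order(self):
        w = np.geomspace(1e-3, 1e3, 200)
        gp = np.full_like(w, 2.0)
        gpp = 40.0 * w / (1 + w * w)  # dominates in a middle window
        xs = crossover_frequencies(ModulusSpectrum(w, gp, gpp))
        assert len(xs) == 2
        assert xs[0].omega < xs[1].omega
        assert xs[0].below == "storage" and xs[0].above == "loss"
        assert xs[1].below == "loss" and xs[1].above == "storage"

    def test_classify_maxwell(self):
        spec = MaxwellFit([5.0], [100.0]).spectrum(np.geomspace(1e-5, 1, 100))
        assert classify_response(spec).label == "maxwell_fluid"

    def test_classify_kelvin_voigt(self):
        w = np.geomspace(1e-5, 1, 100)
        spec = ModulusSpectrum(w, np.full_like(w, 3.0), 0.5 * w)
        assert classify_response(spec).label == "kelvin_voigt_solid"

    def test_classify_viscous(self):
        w = np.geomspace(1e-4, 1, 100)
        spec = ModulusSpectrum(w, np.zeros_like(w), 2.0 * w)
        assert classify_response(spec).label == "viscous_fluid"

    def test_insufficient_bandwidth_indeterminate(self):
        w = np.linspace(1.0, 3.0, 10)
        spec = ModulusSpectrum(w, w, w)
        assert classify_response(spec).label == "indeterminate"
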