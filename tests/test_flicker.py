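"""Flicker-noise spectroscopy: contour extraction, autocorrelation,
spectral decomposition and the Helfrich rigidity fit."""

import numpy as np
import pytest
from numpy.polynomial import legendre as npleg

import membramech as mm
from membramech.flicker import (
    AngularAutocorrelation,
    equatorial_fourier_power,
    helfrich_mode_variance,
    legendre_equatorial_matrix,
)

KAPPA = 1.9e-19
T22 = 295.15


def make_xi(values, R=1.0):
    n = len(values)
    gamma = 2 * np.pi * np.arange(n) / n
    return AngularAutocorrelation(gamma, np.asarray(values, float), R, T22)


class TestAngularAutocorrelation:
    def test_single_cosine_mode_closed_form(self):
        n = 128
        phi = 2 * np.pi * np.arange(n) / n
        a = 0.05
        r = 5.0 + a * np.cos(2 * phi)
        contours = mm.ContourSeries(np.tile(r, (3, 1)), 0.1, 0.16)
        xi = mm.angular_autocorrelation(contours)
        np.testing.assert_allclose(xi.xi, a**2 / 2 * np.cos(2 * xi.gamma), atol=1e-12)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(70)
        r = 5.0 + rng.normal(scale=0.01, size=(500, 128))
        xi = mm.angular_autocorrelation(mm.ContourSeries(r, 0.1, 0.16))
        assert xi.xi[0] == pytest.approx(1e-4, rel=0.2)
        assert np.abs(xi.xi[1:]).max() < 0.1 * xi.xi[0]

    def test_matches_double_loop(self):
        rng = np.random.default_rng(71)
        r = 5.0 + rng.normal(scale=0.02, size=(7, 64))
        contours = mm.ContourSeries(r, 0.1, 0.16)
        xi = mm.angular_autocorrelation(contours)
        R = contours.mean_radius
        u = r - R
        expected = np.array(
            [np.mean(u * np.roll(u, -k, axis=1)) for k in range(64)]
        )
        np.testing.assert_allclose(xi.xi, expected, atol=1e-14)

    def test_xi0_equals_variance_and_parseval(self):
        contours = mm.make_fluctuating_vesicle(n_frames=300, seed=72)
        xi = mm.angular_autocorrelation(contours)
        u = contours.r - contours.mean_radius
        assert xi.xi[0] == pytest.approx(np.mean(u**2), rel=1e-12)
        # Parseval: sum of Fourier mode powers equals the variance
        coeff = np.fft.rfft(u, axis=1) / contours.n_phi
        powers = np.abs(coeff) ** 2
        powers[:, 1:-1] *= 2.0
        assert np.mean(powers.sum(axis=1)) == pytest.approx(np.mean(u**2), rel=1e-9)

    def test_degenerate_contours_warn(self):
        contours = mm.ContourSeries(np.full((5, 64), 5.0), 0.1, 0.16)
        with pytest.warns(UserWarning, match="degenerate"):
            xi = mm.angular_autocorrelation(contours)
        np.testing.assert_array_equal(xi.xi, 0.0)


class TestSpectrumAverage:
    def test_pure_legendre_mode_projection(self):
        n = 256
        gamma = 2 * np.pi * np.arange(n) / n
        xi = make_xi(0.42 * npleg.legval(np.cos(gamma), np.eye(6)[5]))
        spec = mm.spectrum_average(xi, n_modes=12)
        assert spec.legendre_coefficients[5] == pytest.approx(0.42, abs=1e-10)
        others = np.delete(spec.legendre_coefficients, 5)
        assert np.abs(others).max() < 1e-10

    def test_constant_xi_is_pure_monopole(self):
        spec = mm.spectrum_average(make_xi(np.full(128, 0.3)), n_modes=8)
        assert spec.legendre_coefficients[0] == pytest.approx(0.3)
        assert np.abs(spec.legendre_coefficients[1:]).max() < 1e-12

    def test_resynthesis_reproduces_xi(self):
        rng = np.random.default_rng(73)
        n = 128
        # band-limited random autocorrelation (cosine series up to n/2)
        xi_vals = np.zeros(n)
        gamma = 2 * np.pi * np.arange(n) / n
        for m in range(n // 2):
            xi_vals += rng.normal() * np.cos(m * gamma) / (1.0 + m) ** 2
        spec = mm.spectrum_average(make_xi(xi_vals), n_modes=n // 2)
        resynth = npleg.legval(np.cos(gamma), spec.legendre_coefficients)
        np.testing.assert_allclose(resynth, xi_vals, atol=1e-8)

    def test_mode_limit_enforced(self):
        with pytest.raises(ValueError, match="half"):
            mm.spectrum_average(make_xi(np.zeros(64)), n_modes=40)

    def test_legendre_matrix_against_quadrature(self):
        # T[m, l] are the Fourier-cosine coefficients of P_l(cos gamma)
        t = legendre_equatorial_matrix(8)
        gamma = np.linspace(0, 2 * np.pi, 20001)
        for l in (3, 6):
            p = npleg.legval(np.cos(gamma), np.eye(9)[l])
            for m in (l - 2, l):
                num = np.trapezoid(p * np.cos(m * gamma), gamma) / np.pi
                if m == 0:
                    num /= 2.0
                assert t[m, l] == pytest.approx(num, abs=1e-6)


class TestSpectrumStatistical:
    def test_exponential_histogram_recovery(self):
        rng = np.random.default_rng(74)
        n_phi, n_frames = 128, 1000
        means = {3: 4e-4, 5: 1e-4}
        u = np.zeros((n_frames, n_phi))
        phi = 2 * np.pi * np.arange(n_phi) / n_phi
        for m, mean in means.items():
            amp2 = rng.exponential(scale=mean, size=n_frames)
            phase = rng.uniform(0, 2 * np.pi, size=n_frames)
            u += 2 * np.sqrt(amp2)[:, None] * np.cos(
                m * phi[None, :] + phase[:, None]
            )
        contours = mm.ContourSeries(5.0 * (1 + u), 0.1, 0.16)
        spec = mm.spectrum_statistical(contours, n_modes=8)
        for m, mean in means.items():
            assert spec.amplitude_mean[m] == pytest.approx(mean, rel=0.05)

    def test_deterministic_mode_falls_back_with_warning(self):
        n = 128
        phi = 2 * np.pi * np.arange(n) / n
        r = 5.0 * (1 + 0.02 * np.cos(3 * phi))
        contours = mm.ContourSeries(np.tile(r, (200, 1)), 0.1, 0.16)
        with pytest.warns(UserWarning, match="degenerate|raw mean"):
            spec = mm.spectrum_statistical(contours, n_modes=6)
        assert spec.amplitude_mean[3] == pytest.approx(1e-4, rel=1e-6)

    def test_agrees_with_average_approach_on_equilibrium_data(self):
        contours = mm.make_fluctuating_vesicle(
            kappa=KAPPA, n_frames=2000, seed=75, n_phi=256
        )
        stat = mm.spectrum_statistical(contours, n_modes=25)
        avg = mm.spectrum_average(mm.angular_autocorrelation(contours), n_modes=30)
        k_stat = mm.fit_bending_rigidity(stat, mode_range=(3, 20)).kappa
        k_avg = mm.fit_bending_rigidity(avg, mode_range=(3, 20)).kappa
        assert abs(k_stat - k_avg) / k_avg < 0.10


class TestRigidityFit:
    def test_exact_model_amplitudes_recovered(self):
        modes = np.arange(0, 26)
        amps = np.zeros_like(modes, dtype=float)
        amps[2:] = helfrich_mode_variance(modes[2:], KAPPA, 10.0, T22)
        spec = mm.FluctuationSpectrum(modes, amps, "average", 5.0, T22)
        fit = mm.fit_bending_rigidity(spec, mode_range=(3, 20))
        assert abs(fit.kappa - KAPPA) / KAPPA < 0.03
        assert fit.sigma_bar == pytest.approx(10.0, rel=0.05)

    def test_doubling_amplitudes_halves_kappa(self):
        modes = np.arange(0, 26)
        amps = np.zeros_like(modes, dtype=float)
        amps[2:] = helfrich_mode_variance(modes[2:], KAPPA, 10.0, T22)
        spec1 = mm.FluctuationSpectrum(modes, amps, "average", 5.0, T22)
        spec2 = mm.FluctuationSpectrum(modes, 2 * amps, "average", 5.0, T22)
        k1 = mm.fit_bending_rigidity(spec1, mode_range=(3, 20)).kappa
        k2 = mm.fit_bending_rigidity(spec2, mode_range=(3, 20)).kappa
        assert k2 / k1 == pytest.approx(0.5, rel=1e-6)

    def test_agrees_with_grid_search(self):
        contours = mm.make_fluctuating_vesicle(kappa=KAPPA, n_frames=800, seed=76)
        spec = mm.spectrum_statistical(contours, n_modes=25)
        fit = mm.fit_bending_rigidity(spec, mode_range=(3, 20))
        mask = (spec.modes >= 3) & (spec.modes <= 20)
        data = spec.amplitude_mean[mask]
        modes = spec.modes[mask]

        def cost(kappa, sigma_bar):
            model = equatorial_fourier_power(modes, kappa, sigma_bar, T22, 30)
            return np.sum((np.log(model) - np.log(data)) ** 2)

        kappas = fit.kappa * np.linspace(0.9, 1.1, 81)
        sigmas = np.linspace(fit.sigma_bar - 5, fit.sigma_bar + 5, 81)
        grid_cost = np.array([[cost(k, s) for s in sigmas] for k in kappas])
        ik, is_ = np.unravel_index(np.argmin(grid_cost), grid_cost.shape)
        assert abs(kappas[ik] - fit.kappa) / fit.kappa < 0.01
        assert abs(sigmas[is_] - fit.sigma_bar) < 0.25

    def test_invariance_under_rotation_and_frame_permutation(self):
        contours = mm.make_fluctuating_vesicle(kappa=KAPPA, n_frames=400, seed=77)
        rng = np.random.default_rng(0)
        rolled = mm.ContourSeries(
            np.roll(contours.r, 13, axis=1), 0.1, 0.16, T22
        )
        permuted = mm.ContourSeries(
            contours.r[rng.permutation(contours.n_frames)], 0.1, 0.16, T22
        )
        base = mm.fit_bending_rigidity(
            mm.spectrum_statistical(contours, n_modes=25)
        ).kappa
        for other in (rolled, permuted):
            k = mm.fit_bending_rigidity(
                mm.spectrum_statistical(other, n_modes=25)
            ).kappa
            assert k == pytest.approx(base, rel=1e-9)

    def test_too_few_modes_rejected(self):
        modes = np.arange(0, 6)
        amps = np.ones(6, dtype=float) * 1e-5
        spec = mm.FluctuationSpectrum(modes, amps, "average", 5.0, T22)
        with pytest.raises(ValueError, match="4 modes"):
            mm.fit_bending_rigidity(spec, mode_range=(3, 5))


class TestContourExtraction:
    def test_ideal_circle(self):
        stack, _ = mm.make_fluctuating_vesicle(
            kappa=1e-15, radius=5.0, n_frames=3, seed=78, render=True, pixel_size=0.1
        )
        contours = mm.extract_contour(stack, pixel_size=0.1, n_phi=128)
        assert contours.mean_radius == pytest.approx(5.0, abs=0.02)
        # fluctuations are pixel-noise level, far below thermal amplitudes
        assert np.std(contours.r) < 0.05

    def test_ellipse_mode2_amplitude(self):
        n_phi = 180
        phi = 2 * np.pi * np.arange(n_phi) / n_phi
        a, b = 52.0, 48.0
        # radial ellipse contour rendered directly
        r_true = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        size = 131
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        rho = np.hypot(xx - 65, yy - 65)
        ang = np.mod(np.arctan2(yy - 65, xx - 65), 2 * np.pi)
        r_px = np.interp(ang, np.concatenate([phi, [2 * np.pi]]),
                         np.concatenate([r_true, [r_true[0]]]))
        img = 200.0 * np.exp(-((rho - r_px) ** 2) / (2 * 1.2**2))
        contours = mm.extract_contour(img[None], pixel_size=0.1, n_phi=n_phi)
        coeff = np.fft.rfft(contours.r[0]) / n_phi
        measured = 2 * np.abs(coeff[2])
        expected_coeff = 2 * np.abs(np.fft.rfft(r_true * 0.1)[2] / n_phi)
        assert measured == pytest.approx(expected_coeff, rel=0.02)

    def test_off_center_guess_converges(self):
        stack, _ = mm.make_fluctuating_vesicle(
            kappa=1e-15, radius=5.0, n_frames=1, seed=79, render=True, pixel_size=0.1
        )
        c0 = mm.extract_contour(stack, pixel_size=0.1, n_phi=128)
        shape = stack.shape[1]
        c1 = mm.extract_contour(
            stack, pixel_size=0.1, n_phi=128,
            center_guess=(shape // 2 + 10, shape // 2),
        )
        np.testing.assert_allclose(c1.r, c0.r, atol=0.01)


class TestEndToEnd:
    def test_render_extract_fit_recovers_kappa(self):
        stack, truth = mm.make_fluctuating_vesicle(
            kappa=KAPPA, radius=5.0, n_frames=250, seed=80, render=True,
            pixel_size=0.1, n_phi=256,
        )
        contours = mm.extract_contour(stack, pixel_size=0.1, n_phi=256)
        spec = mm.spectrum_statistical(contours, n_modes=20)
        fit = mm.fit_bending_rigidity(spec, mode_range=(3, 12))
        assert abs(fit.kappa - KAPPA) / KAPPA < 0.25
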