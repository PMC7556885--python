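"""Cole-Cole model evaluation, Bose-factor conversion, and per-q fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrosub.spectra import (
    SpectrumGrid,
    bose_factor,
    cole_cole,
    fit_cole_cole,
    peak_frequency,
    read_spectrum,
    to_susceptibility,
    write_spectrum,
)
from hydrosub.synthetic import SpectraSpec, gen_cole_cole_spectra

FREQS = np.geomspace(1e-5, 10.0, 200)


class TestBoseFactor:
    def test_reference_value_1thz_280k(self):
        # h nu / kB T ~ 1.7e-4, so n_B ~ 1/x - 1/2 ~ 5833
        assert bose_factor(1.0, 280.0) == pytest.approx(5833.6, rel=1e-3)

    def test_high_frequency_limit_vanishes(self):
        assert bose_factor(1e6, 280.0) < 1e-60

    def test_classical_limit(self):
        # n_B * (h nu / kB T) -> 1 as nu -> 0
        from hydrosub.spectra import BOLTZMANN_UEV_PER_K, PLANCK_UEV_PER_THZ

        nu = 1e-8
        x = PLANCK_UEV_PER_THZ * nu / (BOLTZMANN_UEV_PER_K * 280.0)
        assert bose_factor(nu, 280.0) * x == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("nu,temp", [(0.0, 280.0), (-1.0, 280.0), (1.0, 0.0)])
    def test_domain_errors(self, nu, temp):
        with pytest.raises(ValueError):
            bose_factor(nu, temp)


class TestColeCole:
    def test_debye_peak_value(self):
        # alpha = 0 at nu = 1/(2 pi tau): chi0 * 1 / (1 + 0 + 1) = chi0 / 2
        assert cole_cole(1.0 / (2 * np.pi), 1.0, 0.0, 1.0) == pytest.approx(0.5)

    def test_broadened_peak_value(self):
        # alpha = 0.5: cos(pi/4) / (2 (1 + sin(pi/4)))
        expected = np.cos(np.pi / 4) / (2 * (1 + np.sin(np.pi / 4)))
        got = cole_cole(1.0 / (2 * np.pi), 1.0, 0.5, 1.0)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.20711, abs=1e-5)

    @settings(derandomize=True, max_examples=50)
    @given(
        tau=st.floats(0.1, 100.0),
        alpha=st.floats(0.0, 0.9),
        chi0=st.floats(0.1, 10.0),
        r=st.floats(1.001, 1e3),
    )
    def test_log_frequency_symmetry(self, tau, alpha, chi0, r):
        """The lineshape is symmetric about the peak on a log axis."""
        nu_p = peak_frequency(tau)
        left = cole_cole(nu_p / r, tau, alpha, chi0)
        right = cole_cole(nu_p * r, tau, alpha, chi0)
        assert left == pytest.approx(right, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        tau=st.floats(0.1, 100.0),
        alpha=st.floats(0.0, 0.7),
        chi0=st.floats(0.1, 10.0),
    )
    def test_nonnegative_and_vanishing_limits(self, tau, alpha, chi0):
        # decay away from the peak goes as x^(1-alpha), slower for larger
        # alpha, hence the 12-decade grid and the alpha <= 0.7 cap
        nus = np.geomspace(1e-12, 1e12, 49)
        vals = cole_cole(nus, tau, alpha, chi0)
        assert np.all(vals >= 0)
        assert vals[0] < 1e-2 * chi0 and vals[-1] < 1e-2 * chi0

    def test_peak_amplitude_decreases_with_alpha(self):
        nu_p = peak_frequency(2.0)
        amps = [cole_cole(nu_p, 2.0, a, 1.0) for a in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert np.all(np.diff(amps) < 0)

    @pytest.mark.parametrize("alpha", [-0.1, 1.0, 1.5])
    def test_alpha_domain_error(self, alpha):
        with pytest.raises(ValueError):
            cole_cole(1.0, 1.0, alpha, 1.0)


class TestPeakFrequency:
    def test_definition(self):
        assert peak_frequency(10.0) == pytest.approx(0.015915, abs=1e-6)
        assert peak_frequency(1.0 / (2 * np.pi)) == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.2, 0.5])
    def test_grid_argmax_matches_closed_form(self, alpha):
        """Brute-force argmax over a dense grid lands on 1/(2 pi tau)."""
        tau = 10.0
        nus = np.geomspace(1e-5, 10.0, 20001)
        vals = cole_cole(nus, tau, alpha, 1.0)
        nu_hat = nus[np.argmax(vals)]
        spacing = nus[1] / nus[0]
        assert peak_frequency(tau) / spacing <= nu_hat <= peak_frequency(tau) * spacing

    def test_domain_error(self):
        with pytest.raises(ValueError):
            peak_frequency(0.0)


class TestSusceptibilityConversion:
    def test_constant_structure_factor_monotone(self):
        grid = SpectrumGrid(
            q_values=[1.0],
            frequencies=FREQS,
            intensity=np.ones((1, FREQS.size)),
            kind="structure_factor",
            temperature=280.0,
        )
        chi = to_susceptibility(grid)
        assert chi.kind == "susceptibility"
        assert np.all(np.diff(chi.intensity[0]) > 0)  # 1/n_B rises with nu

    def test_round_trip_multiplying_back(self):
        rng = np.random.default_rng(0)
        grid = SpectrumGrid(
            q_values=[0.5, 1.0],
            frequencies=FREQS,
            intensity=rng.random((2, FREQS.size)) + 0.1,
            error=rng.random((2, FREQS.size)) * 0.01 + 1e-4,
            kind="structure_factor",
        )
        chi = to_susceptibility(grid)
        nb = bose_factor(FREQS, grid.temperature)
        np.testing.assert_allclose(chi.intensity * nb, grid.intensity, rtol=1e-12)
        np.testing.assert_allclose(chi.error * nb, grid.error, rtol=1e-12)

    def test_generator_round_trip_gives_exact_model(self):
        """Structure-factor synthesis then conversion recovers the model."""
        spec = SpectraSpec(
            q_values=[1.0],
            taus=[5.0],
            alphas=[0.3],
            chi0s=[2.0],
            frequencies=FREQS,
            output_kind="structure_factor",
        )
        chi = to_susceptibility(gen_cole_cole_spectra(spec))
        np.testing.assert_allclose(
            chi.intensity[0], cole_cole(FREQS, 5.0, 0.3, 2.0), rtol=1e-12
        )

    def test_rejects_double_conversion(self):
        grid = SpectrumGrid(
            q_values=[1.0],
            frequencies=FREQS,
            intensity=np.ones((1, FREQS.size)),
            kind="susceptibility",
        )
        with pytest.raises(ValueError):
            to_susceptibility(grid)


class TestFitColeCole:
    def test_noiseless_recovery(self, noiseless_grid):
        grid, spec = noiseless_grid
        for i in range(grid.n_q):
            fit = fit_cole_cole(grid, i)
            assert fit.converged
            assert fit.tau == pytest.approx(spec.taus[i], rel=1e-3)
            assert fit.alpha == pytest.approx(spec.alphas[i], abs=1e-3)
            assert fit.chi0 == pytest.approx(spec.chi0s[i], rel=1e-3)

    def test_debye_slice_recovers_alpha_zero(self):
        spec = SpectraSpec(
            q_values=[1.0], taus=[3.0], alphas=[0.0], chi0s=[1.0], frequencies=FREQS
        )
        fit = fit_cole_cole(gen_cole_cole_spectra(spec), 0)
        assert fit.alpha < 0.01
        assert fit.converged

    def test_scale_equivariance(self, noiseless_grid):
        grid, _ = noiseless_grid
        scaled = SpectrumGrid(
            q_values=grid.q_values,
            frequencies=grid.frequencies,
            intensity=grid.intensity * 37.0,
            kind="susceptibility",
        )
        f1 = fit_cole_cole(grid, 2)
        f2 = fit_cole_cole(scaled, 2)
        assert f2.chi0 == pytest.approx(37.0 * f1.chi0, rel=1e-6)
        assert f2.tau == pytest.approx(f1.tau, rel=1e-6)
        assert f2.alpha == pytest.approx(f1.alpha, abs=1e-6)

    def test_noisy_monte_carlo_tau_recovery(self):
        """Median relative tau error stays below 5% at 5% noise."""
        errors = []
        for seed in range(50):
            spec = SpectraSpec(
                q_values=[1.0],
                taus=[10.0],
                alphas=[0.2],
                chi0s=[1.0],
                frequencies=np.geomspace(1e-4, 1.0, 200),
                noise_level=0.05,
                seed=seed,
            )
            fit = fit_cole_cole(gen_cole_cole_spectra(spec), 0)
            errors.append(abs(fit.tau - 10.0) / 10.0)
        assert np.median(errors) < 0.05

    def test_too_few_points_rejected(self):
        grid = SpectrumGrid(
            q_values=[1.0],
            frequencies=FREQS[:5],
            intensity=np.ones((1, 5)),
            kind="susceptibility",
        )
        with pytest.raises(ValueError):
            fit_cole_cole(grid, 0)

    def test_all_zero_slice_rejected(self):
        grid = SpectrumGrid(
            q_values=[1.0],
            frequencies=FREQS,
            intensity=np.zeros((1, FREQS.size)),
            kind="susceptibility",
        )
        with pytest.raises(ValueError):
            fit_cole_cole(grid, 0)


class TestSpectrumIO:
    def test_write_read_round_trip(self, tmp_path, noiseless_grid):
        grid, _ = noiseless_grid
        path = tmp_path / "spec.tsv"
        write_spectrum(grid, path)
        back = read_spectrum(path, temperature=grid.temperature, kind=grid.kind)
        np.testing.assert_allclose(back.q_values, grid.q_values)
        np.testing.assert_allclose(back.frequencies, grid.frequencies)
        np.testing.assert_allclose(back.intensity, grid.intensity, rtol=1e-12)

    def test_energy_units_conversion(self, tmp_path):
        from hydrosub.spectra import PLANCK_UEV_PER_THZ

        grid = SpectrumGrid(
            q_values=[1.0],
            frequencies=np.array([1.0, 2.0, 4.0]),  # interpreted as ueV on read
            intensity=np.array([[1.0, 2.0, 3.0]]),
            kind="susceptibility",
        )
        path = tmp_path / "ueV.tsv"
        write_spectrum(grid, path)
        back = read_spectrum(path, energy_units="ueV")
        np.testing.assert_allclose(
            back.frequencies, np.array([1.0, 2.0, 4.0]) / PLANCK_UEV_PER_THZ
        )
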