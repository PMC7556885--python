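"""Generators: known-truth spectra and trajectories, determinism, statistics."""

import numpy as np
import pytest
from scipy import stats

from hydrosub.ctrw import WaitingTimeModel
from hydrosub.residence import residence_times
from hydrosub.scaling import compute_msd, fit_msd_exponent
from hydrosub.synthetic import (
    SpectraSpec,
    gen_cole_cole_spectra,
    gen_ctrw_trajectories,
    gen_layered_trajectories,
    heterogeneity_series,
)

FREQS = np.geomspace(1e-4, 10.0, 100)


def _single_bin_model(center=1.0, eps=1e-9):
    """Empirical waits pinned (to within eps) at a single value."""
    return WaitingTimeModel(
        kind="empirical", edges=[center * (1 - eps), center * (1 + eps)], mass=[1.0]
    )


class TestSpectraGenerator:
    def test_debye_cell_value(self):
        spec = SpectraSpec(
            q_values=[1.0],
            taus=[1.0],
            alphas=[0.0],
            chi0s=[1.0],
            frequencies=[1.0 / (2 * np.pi)],
        )
        grid = gen_cole_cole_spectra(spec)
        assert grid.intensity[0, 0] == pytest.approx(0.5)

    def test_broadened_cell_value(self):
        spec = SpectraSpec(
            q_values=[1.0],
            taus=[1.0],
            alphas=[0.5],
            chi0s=[1.0],
            frequencies=[1.0 / (2 * np.pi)],
        )
        grid = gen_cole_cole_spectra(spec)
        assert grid.intensity[0, 0] == pytest.approx(0.20711, abs=1e-5)

    def test_structure_factor_round_trip_identity(self):
        from hydrosub.spectra import to_susceptibility

        kwargs = dict(
            q_values=[0.7, 1.1],
            taus=[8.0, 4.0],
            alphas=[0.2, 0.3],
            chi0s=[1.0, 1.5],
            frequencies=FREQS,
        )
        chi_direct = gen_cole_cole_spectra(SpectraSpec(**kwargs))
        sf = gen_cole_cole_spectra(SpectraSpec(**kwargs, output_kind="structure_factor"))
        np.testing.assert_allclose(
            to_susceptibility(sf).intensity, chi_direct.intensity, rtol=1e-12
        )

    def test_fixed_seed_bit_identical(self):
        kwargs = dict(
            q_values=[1.0],
            taus=[5.0],
            alphas=[0.2],
            chi0s=[1.0],
            frequencies=FREQS,
            noise_level=0.1,
            seed=42,
        )
        a = gen_cole_cole_spectra(SpectraSpec(**kwargs))
        b = gen_cole_cole_spectra(SpectraSpec(**kwargs))
        assert np.array_equal(a.intensity, b.intensity)

    def test_noise_truncation_keeps_intensities_nonnegative(self):
        spec = SpectraSpec(
            q_values=[1.0],
            taus=[5.0],
            alphas=[0.2],
            chi0s=[1.0],
            frequencies=FREQS,
            noise_level=5.0,  # absurdly noisy: truncation must engage
            seed=7,
        )
        assert np.all(gen_cole_cole_spectra(spec).intensity >= 0)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(taus=[-1.0]),
            dict(alphas=[1.0]),
            dict(chi0s=[0.0]),
            dict(frequencies=[-1.0, 1.0]),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(
            q_values=[1.0], taus=[1.0], alphas=[0.2], chi0s=[1.0], frequencies=FREQS
        )
        kwargs.update(bad)
        with pytest.raises(ValueError):
            SpectraSpec(**kwargs)


class TestCTRWTrajectories:
    def test_deterministic_waits_stay_on_lattice(self):
        obs = np.arange(0.5, 20.0, 0.5)
        traj = gen_ctrw_trajectories(
            _single_bin_model(1.0),
            step_length=1.0,
            n_particles=50,
            t_max=20.0,
            dims=1,
            seed=3,
            observation_times=obs,
        )
        x = traj.positions[:, :, 0]
        np.testing.assert_allclose(x, np.round(x), atol=1e-9)  # integer lattice
        # after k whole ps at most k unit jumps have happened
        bound = np.floor(obs + 1e-9)
        assert np.all(np.abs(x) <= bound[None, :] + 1e-9)

    def test_exponential_msd_is_linear(self, exponential_model):
        """Renewal theory: MSD = l0^2 t / <tau> for exponential waits."""
        obs = np.geomspace(1.0, 200.0, 40)
        traj = gen_ctrw_trajectories(
            exponential_model,
            step_length=1.0,
            n_particles=10_000,
            t_max=200.0,
            dims=1,
            seed=5,
            observation_times=obs,
        )
        msd = compute_msd(traj, origin_stride=0)
        sel = (msd.lags >= 10) & (msd.lags <= 100)
        ratio = msd.msd[sel] / msd.lags[sel]
        assert np.all(np.abs(ratio - 1.0) < 0.05)

    def test_pareto_msd_exponent(self, pareto_half_model):
        traj = gen_ctrw_trajectories(
            pareto_half_model,
            step_length=1.0,
            n_particles=10_000,
            t_max=2000.0,
            dims=1,
            seed=6,
        )
        beta = fit_msd_exponent(compute_msd(traj, origin_stride=0))
        assert beta == pytest.approx(0.5, abs=0.05)

    def test_three_dimensional_jumps_have_constant_length(self, exponential_model):
        obs = np.arange(0.05, 30.0, 0.05)  # fine grid: most jumps resolved
        traj = gen_ctrw_trajectories(
            exponential_model,
            step_length=3.5,
            n_particles=20,
            t_max=30.0,
            dims=3,
            seed=9,
            observation_times=obs,
        )
        steps = np.diff(traj.positions, axis=1)
        norms = np.linalg.norm(steps, axis=2).ravel()
        moved = norms[norms > 1e-12]
        # single jumps measure exactly 3.5; rare double jumps within one
        # frame appear as multiples/combinations
        assert moved.size > 0
        single = np.isclose(moved, 3.5)
        assert single.mean() > 0.95

    def test_fixed_seed_bit_identical(self, exponential_model):
        t1 = gen_ctrw_trajectories(exponential_model, n_particles=10, t_max=50.0, seed=11)
        t2 = gen_ctrw_trajectories(exponential_model, n_particles=10, t_max=50.0, seed=11)
        assert np.array_equal(t1.positions, t2.positions)


class TestLayeredTrajectories:
    def test_single_layer_matches_homogeneous_msd(self, exponential_model):
        """One layer model everywhere reduces to the homogeneous walk."""
        obs = np.arange(0.25, 300.0, 0.25)
        layered = gen_layered_trajectories(
            [exponential_model],
            n_particles=800,
            t_max=300.0,
            seed=21,
            observation_times=obs,
        )
        homog = gen_ctrw_trajectories(
            exponential_model,
            step_length=3.5,
            n_particles=800,
            t_max=300.0,
            dims=3,
            seed=22,
            observation_times=obs,
        )
        # compare lateral MSD (x, y are unaffected by the reflecting wall)
        msd_l = compute_msd(layered.lateral(), origin_stride=0)
        msd_h = compute_msd(
            type(homog)(times=homog.times, positions=homog.positions[:, :, :2]),
            origin_stride=0,
        )
        sel = msd_l.lags >= 20
        np.testing.assert_allclose(msd_l.msd[sel], msd_h.msd[sel], rtol=0.15)

    def test_slow_surface_layer_ranks_below_fast_bulk(self):
        slow = WaitingTimeModel(kind="exponential", mean=20.0)
        fast = WaitingTimeModel(kind="exponential", mean=1.0)
        obs = np.arange(0.25, 500.0, 0.25)
        traj = gen_layered_trajectories(
            [slow, fast, fast],
            n_particles=300,
            t_max=500.0,
            seed=23,
            observation_times=obs,
            z_max=10.5,
        )
        from hydrosub.residence import layer_residence_distributions

        dists = layer_residence_distributions(traj)
        assert dists[1].mean() > dists[3].mean()

    def test_deep_start_indistinguishable_from_bulk(self, exponential_model):
        """Started far above the wall, layer structure is irrelevant."""
        obs = np.arange(0.25, 200.0, 0.25)
        deep = gen_layered_trajectories(
            [exponential_model] * 2,
            n_particles=150,
            t_max=200.0,
            seed=24,
            observation_times=obs,
            z_init=100.0,  # > 10 layer thicknesses up
        )
        bulk = gen_ctrw_trajectories(
            exponential_model,
            step_length=3.5,
            n_particles=150,
            t_max=200.0,
            dims=3,
            seed=25,
            observation_times=obs,
        )
        s_deep = residence_times(deep, threshold=3.5).samples
        s_bulk = residence_times(bulk, threshold=3.5).samples
        assert stats.ks_2samp(s_deep, s_bulk).pvalue > 0.01

    def test_empty_layer_list_rejected(self):
        with pytest.raises(ValueError):
            gen_layered_trajectories([], n_particles=10, t_max=10.0, seed=0)


class TestHeterogeneitySeries:
    def test_alpha_rises_as_beta_star_falls(self):
        systems = heterogeneity_series(beta_stars=(1.0, 0.8, 0.6, 0.4))
        alphas = [s["spectra"].alphas[0] for s in systems]
        assert np.all(np.diff(alphas) > 0)

    def test_tau_q_encodes_two_over_beta(self):
        systems = heterogeneity_series(beta_stars=(0.5,))
        spec = systems[0]["spectra"]
        slope = np.polyfit(np.log(spec.q_values), np.log(spec.taus), 1)[0]
        assert -slope == pytest.approx(2.0 / 0.5, rel=1e-9)
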