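"""Synthetic spectra and trajectories with known ground truth.

Every downstream stage of the pipeline — susceptibility conversion,
Cole-Cole fitting, tau(q) scaling, residence-time extraction, the RJ
simulator — is exercised against data generated here, where the true
(tau, alpha, chi0) triples, waiting-time statistics and layer structure
are known exactly.

Three generators:

* :func:`gen_cole_cole_spectra` evaluates the Cole-Cole model on a
  (q, frequency) grid, optionally multiplies by the Bose factor to mimic
  a raw dynamic structure factor, and optionally applies multiplicative
  Gaussian noise (truncated so intensities stay non-negative, mimicking
  how count-statistics uncertainty scales with intensity).
* :func:`gen_ctrw_trajectories` produces constant-step random-jump walks
  in 1 or 3 dimensions with exponential, Pareto or empirical waiting
  times — a stand-in for all-atom MD water trajectories with homogeneous
  waiting statistics.
* :func:`gen_layered_trajectories` places the walkers in the half-space
  above a planar "biomolecular surface" at z = 0 (reflecting boundary)
  and switches the waiting-time model by hydration layer, emulating the
  layer-dependent mobility of interfacial water.

:func:`heterogeneity_series` builds matched (spectra spec, waiting model)
pairs whose mobility heterogeneity increases together: level i uses a
Pareto tail exponent beta*_i and spectra with stretching parameter
alpha_i = 1 - beta*_i and tau(q) = tau0 q^(-2/beta*_i), encoding the
broader-distribution <-> more-sub-diffusive link that the analysis is
meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctrw import WaitingTimeModel, default_observation_times, sample_waiting_time, walk_positions
from .spectra import (
    STRUCTURE_FACTOR,
    SUSCEPTIBILITY,
    SpectrumGrid,
    bose_factor,
    cole_cole,
)
from .trajectories import Trajectory

__all__ = [
    "SpectraSpec",
    "gen_cole_cole_spectra",
    "gen_ctrw_trajectories",
    "gen_layered_trajectories",
    "heterogeneity_series",
    "layered_systems",
]

DEFAULT_STEP_LENGTH = 3.5  # Angstrom; matches the residence displacement threshold


@dataclass
class SpectraSpec:
    """Ground truth for a synthetic susceptibility dataset.

    One Cole-Cole triple (tau ps, alpha, chi0) per wave vector; a common
    strictly increasing positive frequency grid (THz); relative Gaussian
    noise fraction; temperature (K, used only for the Bose factor); and
    whether to emit susceptibility directly or the Bose-weighted
    structure-factor form.
    """

    q_values: np.ndarray
    taus: np.ndarray
    alphas: np.ndarray
    chi0s: np.ndarray
    frequencies: np.ndarray
    noise_level: float = 0.0
    temperature: float = 280.0
    output_kind: str = SUSCEPTIBILITY
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_values", "taus", "alphas", "chi0s", "frequencies"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        nq = self.q_values.size
        if not (self.taus.size == self.alphas.size == self.chi0s.size == nq):
            raise ValueError("need one (tau, alpha, chi0) triple per q")
        if np.any(self.q_values <= 0):
            raise ValueError("wave vectors must be positive")
        if np.any(self.taus <= 0) or np.any(self.chi0s <= 0):
            raise ValueError("tau and chi0 must be positive")
        if np.any((self.alphas < 0) | (self.alphas >= 1)):
            raise ValueError("alpha must lie in [0, 1)")
        if np.any(self.frequencies <= 0) or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be positive and strictly increasing")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.output_kind not in (SUSCEPTIBILITY, STRUCTURE_FACTOR):
            raise ValueError(f"unknown output_kind: {self.output_kind!r}")

    @classmethod
    def from_power_law(
        cls,
        beta_star: float,
        q_values=(0.7, 0.9, 1.1, 1.3, 1.5),
        tau0: float = 5.0,
        alpha: float | None = None,
        chi0: float = 1.0,
        n_freq: int = 200,
        **kwargs,
    ) -> "SpectraSpec":
        """Spectra whose relaxation times follow tau(q) = tau0 q^(-2/beta*).

        ``alpha`` defaults to 1 - beta* (clipped to [0, 0.95]), tying a
        smaller sub-diffusion exponent to a broader lineshape.  The
        frequency grid spans three decades either side of the peaks.
        """
        if not (0 < beta_star <= 1.2):
            raise ValueError("beta_star must be in (0, 1.2]")
        q = np.asarray(q_values, dtype=float)
        taus = tau0 * q ** (-2.0 / beta_star)
        if alpha is None:
            alpha = float(np.clip(1.0 - beta_star, 0.0, 0.95))
        nu_peaks = 1.0 / (2.0 * np.pi * taus)
        freqs = np.geomspace(nu_peaks.min() / 1e3, nu_peaks.max() * 1e3, n_freq)
        return cls(
            q_values=q,
            taus=taus,
            alphas=np.full_like(q, alpha),
            chi0s=np.full_like(q, chi0),
            frequencies=freqs,
            **kwargs,
        )


def gen_cole_cole_spectra(spec: SpectraSpec) -> SpectrumGrid:
    """Evaluate the Cole-Cole forward model on the spec's grid.

    With noise_level = 0 and susceptibility output, every cell equals the
    model exactly.  Noise is multiplicative relative Gaussian, truncated
    at zero: cell = model * max(0, 1 + noise_level * eps).  Structure-
    factor output multiplies each cell by n_B(nu) at the spec temperature,
    so the downstream susceptibility conversion inverts it exactly.  The
    error matrix carries the expected one-sigma level noise_level * model
    (absent when noise_level = 0).
    """
    rng = np.random.default_rng(spec.seed)
    clean = np.empty((spec.q_values.size, spec.frequencies.size))
    for i in range(spec.q_values.size):
        clean[i] = cole_cole(
            spec.frequencies, spec.taus[i], spec.alphas[i], spec.chi0s[i]
        )
    intensity = clean
    error = None
    if spec.noise_level > 0:
        eps = rng.standard_normal(clean.shape)
        intensity = clean * np.maximum(0.0, 1.0 + spec.noise_level * eps)
        error = spec.noise_level * clean
    kind = spec.output_kind
    if kind == STRUCTURE_FACTOR:
        nb = bose_factor(spec.frequencies, spec.temperature)
        intensity = intensity * nb
        error = None if error is None else error * nb
    return SpectrumGrid(
        q_values=spec.q_values.copy(),
        frequencies=spec.frequencies.copy(),
        intensity=intensity,
        error=error,
        temperature=spec.temperature,
        kind=kind,
    )


def gen_ctrw_trajectories(
    model: WaitingTimeModel,
    step_length: float = DEFAULT_STEP_LENGTH,
    n_particles: int = 1000,
    t_max: float = 2000.0,
    dims: int = 1,
    seed: int = 0,
    observation_times: np.ndarray | None = None,
) -> Trajectory:
    """Constant-step random-jump trajectories with i.i.d. waiting times.

    Each jump moves ``step_length`` along a uniformly random axis
    direction (+/- per axis); the particle holds its position between
    jumps, and positions are reported on the observation grid (default:
    log-spaced 1 ps .. t_max plus a uniform fine grid over the first
    10 ps).  Bit-identical under a fixed seed.
    """
    if step_length <= 0 or t_max <= 0 or n_particles < 1:
        raise ValueError("step_length, t_max must be positive; n_particles >= 1")
    rng = np.random.default_rng(seed)
    if observation_times is None:
        observation_times = default_observation_times(t_max)
    obs = np.asarray(observation_times, dtype=float)
    if np.any(obs < 0) or np.any(obs > t_max) or np.any(np.diff(obs) <= 0):
        raise ValueError("observation times must increase within [0, t_max]")
    pos = walk_positions(model, step_length, n_particles, obs, dims, t_max, rng)
    return Trajectory(times=obs, positions=pos)


def gen_layered_trajectories(
    layer_models: list[WaitingTimeModel],
    layer_thickness: float = 3.5,
    n_particles: int = 500,
    t_max: float = 2000.0,
    seed: int = 0,
    step_length: float = DEFAULT_STEP_LENGTH,
    observation_times: np.ndarray | None = None,
    z_init: np.ndarray | float | None = None,
    z_max: float | None = None,
) -> Trajectory:
    """3-D walkers above a reflecting plane with layer-dependent waits.

    Before each jump the particle's current layer index
    floor(z / layer_thickness) selects its waiting-time model (layers
    beyond the list reuse the last model, the "bulk" entry).  Jumps are
    constant-length axis moves; a move below the surface is reflected
    (z -> -z).  ``z_init`` sets starting heights (scalar or per-particle
    array); the default spreads particles uniformly over the modelled
    layers.  x and y start at 0.

    ``z_max`` optionally adds a reflecting ceiling, turning the half-space
    into a slab: a hydrated powder or film holds only a few layers of
    water, so particles cannot wander off into unlimited bulk.  The
    default (None) keeps the open half-space.
    """
    if not layer_models:
        raise ValueError("need at least one layer waiting-time model")
    if layer_thickness <= 0:
        raise ValueError("layer_thickness must be positive")
    if step_length <= 0 or t_max <= 0 or n_particles < 1:
        raise ValueError("step_length, t_max must be positive; n_particles >= 1")
    rng = np.random.default_rng(seed)
    if observation_times is None:
        observation_times = default_observation_times(t_max)
    obs = np.asarray(observation_times, dtype=float)
    if np.any(obs < 0) or np.any(obs > t_max) or np.any(np.diff(obs) <= 0):
        raise ValueError("observation times must increase within [0, t_max]")

    n_layers = len(layer_models)
    if z_max is not None:
        if z_max <= step_length:
            raise ValueError("z_max must exceed the step length")
        if z_init is None:
            z_init = rng.uniform(0.0, z_max, size=n_particles)
    if z_init is None:
        z0 = rng.uniform(0.0, n_layers * layer_thickness, size=n_particles)
    else:
        z0 = np.broadcast_to(np.asarray(z_init, dtype=float), (n_particles,)).copy()
        if np.any(z0 < 0):
            raise ValueError("initial heights must be non-negative")

    pos = np.zeros((n_particles, 3))
    pos[:, 2] = z0
    t_now = np.zeros(n_particles)
    ptr = np.zeros(n_particles, dtype=int)  # next observation index to fill
    out = np.empty((n_particles, obs.size, 3))
    active = np.ones(n_particles, dtype=bool)

    while np.any(active):
        ids = np.nonzero(active)[0]
        layer = np.minimum(
            (pos[ids, 2] // layer_thickness).astype(int), n_layers - 1
        )
        waits = np.empty(ids.size)
        for li in np.unique(layer):
            sel = layer == li
            waits[sel] = sample_waiting_time(layer_models[li], rng, size=int(sel.sum()))
        t_new = t_now[ids] + waits
        # the particle sits at its pre-jump position throughout the wait
        new_ptr = np.searchsorted(obs, np.minimum(t_new, t_max), side="right")
        moved = ids[new_ptr > ptr[ids]]
        for i, stop in zip(moved, new_ptr[new_ptr > ptr[ids]]):
            out[i, ptr[i] : stop] = pos[i]
            ptr[i] = stop
        # jump at the end of the wait
        u = rng.integers(0, 6, size=ids.size)
        axis, sign = u >> 1, (2 * (u & 1) - 1).astype(float)
        pos[ids, axis] += sign * step_length
        pos[ids, 2] = np.abs(pos[ids, 2])  # reflecting boundary at z = 0
        if z_max is not None:  # reflecting ceiling of the water slab
            over = pos[ids, 2] > z_max
            pos[ids[over], 2] = 2.0 * z_max - pos[ids[over], 2]
        t_now[ids] = t_new
        done = ids[(t_new > t_max) | (ptr[ids] >= obs.size)]
        active[done] = False
        # a finished particle may still owe trailing observations
        for i in done:
            if ptr[i] < obs.size:
                out[i, ptr[i] :] = pos[i]
                ptr[i] = obs.size
    return Trajectory(times=obs, positions=out)


def layered_systems(
    level_means=((4.0, 2.0), (8.0, 4.0, 2.0), (16.0, 8.0, 4.0, 2.0), (16.0, 2.0, 1.0)),
    layer_thickness: float = 3.5,
) -> list[dict]:
    """Slab systems of increasing layer-mobility contrast.

    Each level lists per-layer exponential waiting-time means (ps), slowest
    at the surface; the slab ceiling sits at the top of the last modelled
    layer, emulating a water film that holds only those layers.  The
    mobility contrast between surface and bulk layers grows along the
    series, so the extracted residence-time distributions broaden and the
    lateral MSD exponent over the 5-1000 ps window drops below 1.

    The default series stays below ~16x surface-to-bulk contrast: beyond
    that, consecutive slow-layer waits of one particle become strongly
    correlated and the i.i.d.-waiting reduction behind the coarse-grained
    jump model starts to lose accuracy.
    """
    systems = []
    for means in level_means:
        systems.append(
            {
                "models": [WaitingTimeModel(kind="exponential", mean=m) for m in means],
                "z_max": len(means) * layer_thickness,
                "means": tuple(float(m) for m in means),
            }
        )
    return systems


def heterogeneity_series(
    beta_stars=(1.0, 0.8, 0.6, 0.4),
    tau0: float = 5.0,
    t_min: float = 0.01,
    noise_level: float = 0.0,
    seed: int = 0,
) -> list[dict]:
    """Matched spectra/waiting-model systems of increasing heterogeneity.

    Level i (beta* decreasing) pairs a Pareto waiting model of tail
    exponent beta*_i (an exponential of mean 1 ps when beta* = 1, since
    any finite-mean wait gives normal diffusion) with a spectra spec
    whose stretching parameter is alpha_i = 1 - beta*_i and whose
    relaxation times scale as tau(q) = tau0 q^(-2/beta*_i).  ``t_min``
    defaults to 0.01 ps, two to three decades below the standard 5-1000
    ps fit window, so the CTRW asymptotic regime MSD ~ t^beta* holds
    throughout the window.
    """
    systems = []
    for i, bs in enumerate(beta_stars):
        if bs >= 1.0:
            model = WaitingTimeModel(kind="exponential", mean=1.0)
        else:
            model = WaitingTimeModel(kind="pareto", tail_exponent=bs, t_min=t_min)
        spec = SpectraSpec.from_power_law(
            beta_star=bs, tau0=tau0, noise_level=noise_level, seed=seed + i
        )
        systems.append({"beta_star": float(bs), "model": model, "spectra": spec})
    return systems
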