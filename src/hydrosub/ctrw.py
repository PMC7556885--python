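"""Coarse-grained random-jump (RJ) simulator: CTRW with constant step length.

A particle performs jumps of fixed length l0, going forwards or backwards
with equal probability (in d dimensions: a uniformly chosen axis
direction), and waits between consecutive jumps for a time drawn
independently from a waiting-time distribution.  Exponential waits give
normal diffusion, MSD = (l0^2 / <tau>) t; heavy-tailed Pareto waits
psi(t) = beta t_min^beta t^-(1+beta) with 0 < beta < 1 have diverging mean
and give sub-diffusion, MSD ~ t^beta.  An empirical mode draws waits from
a log-binned residence-time distribution, which is how the simulator is
driven by residence statistics extracted from trajectories.

The simulation is event-driven (no fixed time step): per particle the
event times are the cumulative sum of waits, and the position reported at
an observation time is the position after the last jump at or before it
(wait-then-jump convention: the particle sits still during a wait and
jumps at its end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma

from .residence import ResidenceDistribution
from .scaling import DEFAULT_MSD_WINDOW, MSDCurve, fit_msd_exponent

__all__ = [
    "WaitingTimeModel",
    "RJConfig",
    "RJResult",
    "sample_waiting_time",
    "default_observation_times",
    "simulate_rj",
    "beta_from_residence",
    "beta_vs_distribution",
    "walk_positions",
]

EXPONENTIAL = "exponential"
PARETO = "pareto"
EMPIRICAL = "empirical"


@dataclass(frozen=True)
class WaitingTimeModel:
    """Waiting-time distribution between jumps.

    kind = "exponential": ``mean`` (ps) > 0.
    kind = "pareto": density beta t_min^beta t^-(1+beta) on [t_min, inf),
        with ``tail_exponent`` beta in (0, 1] and ``t_min`` (ps) > 0.
    kind = "empirical": log-binned histogram (``edges``, ``mass``); a draw
        picks a bin proportional to its mass and is then log-uniform
        within the bin.
    """

    kind: str
    mean: float | None = None
    tail_exponent: float | None = None
    t_min: float | None = None
    edges: np.ndarray | None = field(default=None, compare=False)
    mass: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind == EXPONENTIAL:
            if self.mean is None or not self.mean > 0:
                raise ValueError("exponential model needs mean > 0")
        elif self.kind == PARETO:
            if self.tail_exponent is None or not (0.0 < self.tail_exponent <= 1.0):
                raise ValueError("pareto tail_exponent must lie in (0, 1]")
            if self.t_min is None or not self.t_min > 0:
                raise ValueError("pareto t_min must be positive")
        elif self.kind == EMPIRICAL:
            if self.edges is None or self.mass is None:
                raise ValueError("empirical model needs edges and mass")
            edges = np.asarray(self.edges, dtype=float)
            mass = np.asarray(self.mass, dtype=float)
            if mass.size != edges.size - 1 or np.any(np.diff(edges) <= 0):
                raise ValueError("invalid empirical histogram")
            if np.any(edges <= 0):
                raise ValueError("empirical bin edges must be positive")
            if np.any(mass < 0) or mass.sum() <= 0:
                raise ValueError("empirical masses must be non-negative, not all zero")
            object.__setattr__(self, "edges", edges)
            object.__setattr__(self, "mass", mass / mass.sum())
        else:
            raise ValueError(f"unknown waiting-time model kind: {self.kind!r}")

    @classmethod
    def from_distribution(cls, dist: ResidenceDistribution) -> "WaitingTimeModel":
        """Empirical waiting model backed by a residence-time distribution."""
        return cls(kind=EMPIRICAL, edges=dist.edges, mass=dist.mass)

    @classmethod
    def from_distribution_file(cls, path) -> "WaitingTimeModel":
        """Read a delimited residence-distribution table (bin_lo, bin_hi, mass)."""
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"bin_lo", "bin_hi", "mass"}
        if not required.issubset(df.columns):
            raise ValueError(f"distribution file must have columns {sorted(required)}")
        df = df.sort_values("bin_lo")
        edges = np.append(df["bin_lo"].to_numpy(), df["bin_hi"].to_numpy()[-1])
        return cls(kind=EMPIRICAL, edges=edges, mass=df["mass"].to_numpy())

    def mean_wait(self) -> float:
        """Mean waiting time; infinite for a Pareto tail exponent <= 1."""
        if self.kind == EXPONENTIAL:
            return float(self.mean)
        if self.kind == PARETO:
            return np.inf  # tail_exponent <= 1: the mean diverges
        a, b = self.edges[:-1], self.edges[1:]
        return float(np.sum(self.mass * (b - a) / np.log(b / a)))

    def expected_jumps(self, t: float) -> float:
        """Rough expected number of renewals by time t (used for chunk sizing)."""
        if self.kind == PARETO:
            b, tm = self.tail_exponent, self.t_min
            if b < 1.0:
                return max(1.0, (t / tm) ** b / (_gamma(1 + b) * _gamma(1 - b)))
            return max(1.0, t / (tm * max(np.log(max(t / tm, np.e)), 1.0)))
        return max(1.0, t / self.mean_wait())


def sample_waiting_time(
    model: WaitingTimeModel, rng: np.random.Generator, size=None
):
    """Draw waiting times (ps) by inverse CDF; scalar when ``size`` is None."""
    n = 1 if size is None else size
    if model.kind == EXPONENTIAL:
        out = rng.exponential(model.mean, size=n)
    elif model.kind == PARETO:
        u = rng.random(size=n)
        out = model.t_min * u ** (-1.0 / model.tail_exponent)
    else:
        bins = rng.choice(model.mass.size, size=n, p=model.mass)
        u = rng.random(size=n)
        lo = np.log(model.edges[:-1])[bins]
        hi = np.log(model.edges[1:])[bins]
        out = np.exp(lo + u * (hi - lo))
    return float(out[0]) if size is None else out


@dataclass
class RJConfig:
    """Configuration of one random-jump run."""

    model: WaitingTimeModel
    step_length: float = 3.5  # Angstrom
    n_particles: int = 10_000
    t_max: float = 2000.0  # ps
    observation_times: np.ndarray | None = None
    fit_window: tuple[float, float] = DEFAULT_MSD_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.observation_times is None:
            self.observation_times = default_observation_times(self.t_max)
        self.observation_times = np.asarray(self.observation_times, dtype=float)
        obs = self.observation_times
        if np.any(obs < 0) or np.any(obs > self.t_max) or np.any(np.diff(obs) <= 0):
            raise ValueError("observation times must increase within [0, t_max]")


@dataclass
class RJResult:
    """Ensemble MSD of one RJ run, its fitted exponent, jump statistics."""

    msd: MSDCurve
    beta: float
    jumps_mean: float
    jumps_max: int
    degenerate: bool = False


def default_observation_times(
    t_max: float, n_log: int = 64, fine_dt: float = 0.25, fine_until: float = 10.0
) -> np.ndarray:
    """Log-spaced grid from 1 ps to t_max plus a uniform fine grid to 10 ps."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    coarse = np.geomspace(1.0, t_max, n_log) if t_max > 1 else np.array([t_max])
    fine = np.arange(fine_dt, min(fine_until, t_max) + fine_dt / 2, fine_dt)
    return np.unique(np.round(np.concatenate([fine, coarse]), 12))


def _event_times(
    model: WaitingTimeModel, n: int, t_max: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, K) cumulative event times; every row's last entry exceeds t_max."""
    k0 = int(1.3 * model.expected_jumps(t_max)) + 8
    et = np.cumsum(sample_waiting_time(model, rng, size=(n, k0)), axis=1)
    while et[:, -1].min() <= t_max:
        k_ext = max(8, et.shape[1] // 2)
        ext = np.cumsum(sample_waiting_time(model, rng, size=(n, k_ext)), axis=1)
        et = np.concatenate([et, et[:, -1:] + ext], axis=1)
    return et


def _counts_at(event_times: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Number of events at or before each observation time, per row.

    Rows of ``event_times`` are sorted; a single searchsorted over an
    offset-flattened array replaces a per-row loop.
    """
    n, k = event_times.shape
    off = float(event_times.max()) + float(obs.max()) + 1.0
    shifts = off * np.arange(n)[:, None]
    flat = (event_times + shifts).ravel()
    queries = (obs[None, :] + shifts).ravel()
    idx = np.searchsorted(flat, queries, side="right").reshape(n, obs.size)
    return idx - k * np.arange(n)[:, None]


def walk_positions(
    model: WaitingTimeModel,
    step_length: float,
    n_particles: int,
    obs_times: np.ndarray,
    dims: int,
    t_max: float,
    rng: np.random.Generator,
    block: int = 1024,
) -> np.ndarray:
    """Positions (n_particles, n_obs, dims) of constant-step random jumps.

    Jump directions are uniform over the 2*dims axis directions; particles
    start at the origin and hold their position between jumps.
    """
    if dims not in (1, 2, 3):
        raise ValueError("dims must be 1, 2 or 3")
    obs = np.asarray(obs_times, dtype=float)
    out = np.empty((n_particles, obs.size, dims))
    for start in range(0, n_particles, block):
        b = min(block, n_particles - start)
        et = _event_times(model, b, t_max, rng)
        k = et.shape[1]
        u = rng.integers(0, 2 * dims, size=(b, k))
        sign = (2 * (u & 1) - 1).astype(float) * step_length
        if dims == 1:
            cum = np.cumsum(sign, axis=1)[:, :, None]
        else:
            steps = np.zeros((b, k, dims))
            np.put_along_axis(steps, (u >> 1)[:, :, None], sign[:, :, None], axis=2)
            cum = np.cumsum(steps, axis=1)
        counts = _counts_at(et, obs)
        idx = np.maximum(counts - 1, 0)
        pos = np.take_along_axis(cum, idx[:, :, None], axis=1)
        pos[counts == 0] = 0.0
        out[start : start + b] = pos
    return out


def simulate_rj(config: RJConfig) -> RJResult:
    """Run the RJ model and measure the ensemble MSD and its exponent.

    The MSD is the pure ensemble average <x(t)^2> over particles, all
    starting at the origin at t = 0 (no sliding time origins: for
    heavy-tailed waits the process ages, and time-averaging would push the
    apparent exponent towards 1).  ``beta`` is a log-log power-law fit of
    the MSD over ``config.fit_window``, clipped to observation times with
    positive MSD; the result is flagged degenerate when fewer than three
    such points exist (e.g. when no particle has jumped).
    """
    rng = np.random.default_rng(config.seed)
    obs = config.observation_times
    n = config.n_particles
    msd_acc = np.zeros(obs.size)
    jumps_sum, jumps_max = 0.0, 0
    block = 1024
    for start in range(0, n, block):
        b = min(block, n - start)
        et = _event_times(config.model, b, config.t_max, rng)
        sign = (2.0 * rng.integers(0, 2, size=et.shape) - 1.0) * config.step_length
        cum = np.cumsum(sign, axis=1)
        counts = _counts_at(et, obs)
        idx = np.maximum(counts - 1, 0)
        x = np.take_along_axis(cum, idx, axis=1)
        x[counts == 0] = 0.0
        msd_acc += np.sum(x * x, axis=0)
        n_jumps = _counts_at(et, np.array([config.t_max]))[:, 0]
        jumps_sum += float(n_jumps.sum())
        jumps_max = max(jumps_max, int(n_jumps.max()))
    msd = msd_acc / n
    curve = MSDCurve(lags=obs, msd=msd, n_origins=np.full(obs.size, n))
    usable = (msd > 0) & (obs >= config.fit_window[0]) & (obs <= config.fit_window[1])
    degenerate = bool(usable.sum() < 3)
    beta = np.nan
    if not degenerate:
        beta = fit_msd_exponent(curve, config.fit_window)
    return RJResult(
        msd=curve,
        beta=beta,
        jumps_mean=jumps_sum / n,
        jumps_max=jumps_max,
        degenerate=degenerate,
    )


def beta_from_residence(
    traj,
    threshold: float = 3.5,
    step_length: float = 3.5,
    n_particles: int = 5000,
    t_max: float | None = None,
    seed: int = 0,
    fit_window: tuple[float, float] = DEFAULT_MSD_WINDOW,
    bins_per_decade: int = 10,
) -> RJResult:
    """Drive the RJ model with residence times extracted from a trajectory.

    Extracts P(tau_res) at the displacement ``threshold``, wraps it as an
    empirical waiting model and simulates constant-step jumps of length
    ``step_length``.  This is the trajectory-to-coarse-grained handoff:
    if mobility heterogeneity (the breadth of P(tau_res)) is what causes
    the sub-diffusion, the RJ exponent should match a direct MSD fit of
    the source trajectory.
    """
    from .residence import residence_distribution, residence_times

    rts = residence_times(traj, threshold=threshold)
    dist = residence_distribution(rts, bins_per_decade=bins_per_decade)
    model = WaitingTimeModel.from_distribution(dist)
    if t_max is None:
        t_max = float(traj.times[-1])
    cfg = RJConfig(
        model=model,
        step_length=step_length,
        n_particles=n_particles,
        t_max=t_max,
        fit_window=fit_window,
        seed=seed,
    )
    return simulate_rj(cfg)


def beta_vs_distribution(
    models: list[WaitingTimeModel], template: RJConfig
) -> pd.DataFrame:
    """Run simulate_rj for each waiting model with a shared configuration.

    Every run reuses the template's step length, particle count, horizon,
    observation grid, fit window and seed; returns one row per model, in
    input order, with the fitted sub-diffusive exponent.
    """
    if len(models) < 1:
        raise ValueError("need at least one waiting-time model")
    rows = []
    for i, model in enumerate(models):
        cfg = RJConfig(
            model=model,
            step_length=template.step_length,
            n_particles=template.n_particles,
            t_max=template.t_max,
            observation_times=template.observation_times.copy(),
            fit_window=template.fit_window,
            seed=template.seed,
        )
        res = simulate_rj(cfg)
        rows.append(
            {
                "index": i,
                "kind": model.kind,
                "beta": res.beta,
                "jumps_mean": res.jumps_mean,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)
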