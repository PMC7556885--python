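"""From relaxation times and trajectories to the sub-diffusion exponent.

Two independent routes to the anomalous-diffusion exponent beta in
<x^2(t)> ~ t^beta:

* q-scaling: the relaxation time from susceptibility fits follows a power
  law tau ~ q^-n; since tau is the time to diffuse a distance ~ 2 pi / q,
  <x^2(t)> ~ t^(2/n), i.e. beta = 2/n.  n = 2 is Fickian diffusion,
  n > 2 signals sub-diffusion.
* direct: a log-log power-law fit to the mean-squared displacement over a
  time window (default 5-1000 ps).

The module also averages the Cole-Cole stretching parameter alpha over a
q-band (default 0.7-1.5 inverse Angstrom) as a heterogeneity summary, and
converts hydration level h (gram water per gram protein) into the
bulk-like water fraction, treating the first two hydration layers
(~1.2 g/g) as bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import ColeColeParams
from .trajectories import Trajectory

__all__ = [
    "ScalingResult",
    "MSDCurve",
    "fit_power_law_tau_q",
    "beta_from_n",
    "compute_msd",
    "fit_msd_exponent",
    "average_alpha",
    "bulk_like_fraction",
]

DEFAULT_Q_BAND = (0.7, 1.5)  # inverse Angstrom
DEFAULT_MSD_WINDOW = (5.0, 1000.0)  # ps
DEFAULT_BOUND_WATER = 1.2  # g water / g protein in the first two layers
MAX_ORIGINS_PER_LAG = 10_000


@dataclass
class ScalingResult:
    """Power-law exponent n of tau(q), derived beta = 2/n, diagnostics."""

    n: float
    beta: float
    q_range: tuple[float, float]
    slope_stderr: float = np.nan
    r_squared: float = np.nan
    alpha_bar: float | None = None

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError("exponent n must be positive")
        if abs(self.beta - 2.0 / self.n) > 1e-12:
            raise ValueError("beta must equal 2/n")


@dataclass
class MSDCurve:
    """Mean-squared displacement versus lag time.

    lags : (m,) ps, strictly increasing, non-negative.
    msd : (m,) Angstrom^2, non-negative (0 at lag 0).
    n_origins : (m,) time origins averaged at each lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_origins: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_origins = np.asarray(self.n_origins, dtype=int)
        if not (self.lags.shape == self.msd.shape == self.n_origins.shape):
            raise ValueError("lags, msd and n_origins must align")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0) or not np.all(np.isfinite(self.msd)):
            raise ValueError("MSD values must be finite and non-negative")
        zero = self.lags == 0
        if np.any(self.msd[zero] != 0):
            raise ValueError("MSD at zero lag must be zero")


def fit_power_law_tau_q(
    taus: list[tuple[float, float]] | np.ndarray,
    q_range: tuple[float, float] = (0.0, np.inf),
) -> ScalingResult:
    """Fit tau ~ q^-n by ordinary least squares of ln(tau) on ln(q).

    ``taus`` is a sequence of (q, tau) pairs; only pairs with q inside
    ``q_range`` (inclusive) enter the fit, which is unweighted in log-log
    space.  Returns n = -slope together with the slope standard error and
    R^2 of the regression.
    """
    arr = np.asarray(taus, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("taus must be (q, tau) pairs")
    if np.any(arr <= 0):
        raise ValueError("q and tau must all be positive")
    lo, hi = q_range
    keep = (arr[:, 0] >= lo) & (arr[:, 0] <= hi)
    if keep.sum() < 3:
        raise ValueError("need at least 3 (q, tau) pairs inside q_range")
    q, tau = arr[keep, 0], arr[keep, 1]
    reg = stats.linregress(np.log(q), np.log(tau))
    n = -float(reg.slope)
    if n <= 0:
        raise ValueError("fitted exponent n is non-positive; tau does not decay with q")
    return ScalingResult(
        n=n,
        beta=beta_from_n(n),
        q_range=(float(q.min()), float(q.max())),
        slope_stderr=float(reg.stderr),
        r_squared=float(reg.rvalue**2),
    )


def beta_from_n(n: float) -> float:
    """Sub-diffusion exponent beta = 2/n from the tau(q) power-law exponent."""
    if not n > 0:
        raise ValueError("n must be positive")
    return 2.0 / n


def compute_msd(
    traj: Trajectory,
    lags: np.ndarray | None = None,
    origin_stride: int = 1,
    max_origins: int = MAX_ORIGINS_PER_LAG,
) -> MSDCurve:
    """MSD averaged over particles and sliding time origins.

    Requires a uniformly spaced time grid; lag times are matched to the
    nearest whole-frame offsets.  For each lag the squared displacement
    |r(t0 + lag) - r(t0)|^2 is averaged over all particles and over time
    origins t0 stepped by ``origin_stride`` frames (subsampled evenly once
    more than ``max_origins`` origins would be used).  ``origin_stride``
    of zero keeps only the first frame as origin (pure ensemble MSD, the
    right choice for ageing processes such as heavy-tailed CTRW); in that
    mode the time grid need not be uniform and lags are the frame times.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    if origin_stride == 0:
        disp = traj.positions - traj.positions[:, :1, :]
        msd0 = np.mean(np.sum(disp * disp, axis=2), axis=0)
        lags0 = traj.times - traj.times[0]
        keep = lags0 > 0
        if lags is not None:
            lags = np.asarray(lags, dtype=float)
            if np.any(lags > traj.duration * (1 + 1e-9)):
                raise ValueError("lag exceeds trajectory span")
            keep &= np.isin(lags0, lags) | np.array(
                [np.any(np.isclose(t, lags)) for t in lags0]
            )
        return MSDCurve(
            lags=lags0[keep],
            msd=msd0[keep],
            n_origins=np.ones(int(keep.sum()), dtype=int),
        )
    dt = np.diff(traj.times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("compute_msd requires a uniform time grid")
    dt = float(dt[0])
    span = traj.duration
    if lags is None:
        offsets = np.arange(1, traj.n_frames)
    else:
        lags = np.asarray(lags, dtype=float)
        if np.any(lags > span * (1 + 1e-9)):
            raise ValueError("lag exceeds trajectory span")
        offsets = np.unique(np.rint(lags / dt).astype(int))
        offsets = offsets[offsets >= 1]
        if offsets.size == 0:
            raise ValueError("no usable lags after matching to the frame grid")
    pos = traj.positions
    msd = np.empty(offsets.size)
    n_origins = np.empty(offsets.size, dtype=int)
    for i, k in enumerate(offsets):
        if origin_stride == 0:
            origins = np.array([0])
        else:
            origins = np.arange(0, traj.n_frames - k, origin_stride)
            if origins.size > max_origins:
                origins = origins[:: int(np.ceil(origins.size / max_origins))]
        disp = pos[:, origins + k, :] - pos[:, origins, :]
        msd[i] = np.mean(np.sum(disp * disp, axis=2))
        n_origins[i] = origins.size
    return MSDCurve(lags=offsets * dt, msd=msd, n_origins=n_origins)


def fit_msd_exponent(
    msd: MSDCurve, window: tuple[float, float] = DEFAULT_MSD_WINDOW
) -> float:
    """Power-law exponent of MSD ~ t^beta inside a time window (log-log OLS)."""
    lo, hi = window
    keep = (msd.lags >= lo) & (msd.lags <= hi)
    if keep.sum() < 3:
        raise ValueError("need at least 3 lags inside the fit window")
    if np.any(msd.msd[keep] <= 0):
        raise ValueError("MSD must be positive throughout the fit window")
    reg = stats.linregress(np.log(msd.lags[keep]), np.log(msd.msd[keep]))
    return float(reg.slope)


def average_alpha(
    fits: list[ColeColeParams], q_range: tuple[float, float] = DEFAULT_Q_BAND
) -> float:
    """Unweighted mean Cole-Cole alpha over converged fits with q in the band."""
    lo, hi = q_range
    alphas = [f.alpha for f in fits if f.converged and lo <= f.q <= hi]
    if not alphas:
        raise ValueError("no converged fits inside the q band")
    return float(np.mean(alphas))


def bulk_like_fraction(h: float, bound_water: float = DEFAULT_BOUND_WATER) -> float:
    """Fraction of water that is bulk-like at hydration level ``h`` (g/g).

    The first two hydration layers bind ``bound_water`` grams of water per
    gram of protein; everything beyond is counted bulk-like:
    max(0, (h - bound_water) / h).
    """
    if h <= 0:
        raise ValueError("hydration level must be positive")
    if bound_water < 0:
        raise ValueError("bound_water must be non-negative")
    return max(0.0, (h - bound_water) / h)
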