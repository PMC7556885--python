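"""Neutron susceptibility spectra and Cole-Cole relaxation fitting.

Quasi-elastic neutron scattering yields the dynamic structure factor
S(q, nu) on a grid of wave vectors q (inverse Angstrom) and frequencies nu
(THz).  Dividing by the Bose occupation factor n_B(nu) turns it into the
imaginary susceptibility chi''(q, nu), in which a relaxation process with
characteristic time tau appears as a peak at nu_peak = 1/(2 pi tau).  The
peak shape is modelled by the Cole-Cole distribution function

    chi''(nu) = chi0 * x^(1-a) cos(pi a / 2)
                / [1 + 2 x^(1-a) sin(pi a / 2) + x^(2(1-a))],
    x = 2 pi nu tau,

where the stretching parameter ``a`` (alpha) in [0, 1) measures how broad
the underlying distribution of relaxation times is: alpha = 0 recovers the
single-timescale Debye form, larger alpha means a more heterogeneous
ensemble of relaxers.

This module houses the grid container, the S -> chi'' conversion, the
Cole-Cole forward model and its per-q weighted least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PLANCK_UEV_PER_THZ",
    "BOLTZMANN_UEV_PER_K",
    "SpectrumGrid",
    "ColeColeParams",
    "bose_factor",
    "to_susceptibility",
    "cole_cole",
    "peak_frequency",
    "fit_cole_cole",
    "read_spectrum",
    "write_spectrum",
    "fits_to_frame",
]

#: Planck constant, microelectronvolt per THz (E = h nu).
PLANCK_UEV_PER_THZ = 4.135668
#: Boltzmann constant, microelectronvolt per kelvin.
BOLTZMANN_UEV_PER_K = 86.17333

STRUCTURE_FACTOR = "structure_factor"
SUSCEPTIBILITY = "susceptibility"

#: Fit bounds: tau (ps), alpha (dimensionless), chi0 (spectrum units).
TAU_BOUNDS = (1e-3, 1e6)
ALPHA_BOUNDS = (0.0, 0.99)
_ALPHA_STARTS = (0.05, 0.2, 0.5)


@dataclass
class SpectrumGrid:
    """Intensities on a (q, frequency) grid.

    Parameters
    ----------
    q_values : array, shape (nq,)
        Wave vectors in inverse Angstrom.
    frequencies : array, shape (nf,)
        Frequencies in THz, strictly increasing and positive.
    intensity : array, shape (nq, nf)
        One intensity per (q, nu) cell.
    error : array or None
        Optional one-sigma uncertainties, same shape as ``intensity``.
    temperature : float
        Sample temperature in kelvin (needed for the Bose factor).
    kind : str
        Either ``"structure_factor"`` or ``"susceptibility"``.
    """

    q_values: np.ndarray
    frequencies: np.ndarray
    intensity: np.ndarray
    error: np.ndarray | None = None
    temperature: float = 280.0
    kind: str = SUSCEPTIBILITY

    def __post_init__(self) -> None:
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
        if self.kind not in (STRUCTURE_FACTOR, SUSCEPTIBILITY):
            raise ValueError(f"unknown spectrum kind: {self.kind!r}")
        if self.intensity.shape != (self.q_values.size, self.frequencies.size):
            raise ValueError(
                "intensity shape "
                f"{self.intensity.shape} inconsistent with axes "
                f"({self.q_values.size}, {self.frequencies.size})"
            )
        if self.error is not None and self.error.shape != self.intensity.shape:
            raise ValueError("error matrix shape differs from intensity")
        if np.any(self.frequencies <= 0) or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.kind == STRUCTURE_FACTOR and np.any(self.intensity < 0):
            raise ValueError("structure-factor intensities must be non-negative")

    @property
    def n_q(self) -> int:
        return self.q_values.size

    def slice(self, q_index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        """Return (frequencies, intensity, error) for one q row."""
        err = None if self.error is None else self.error[q_index]
        return self.frequencies, self.intensity[q_index], err


@dataclass
class ColeColeParams:
    """Fitted Cole-Cole triple for one q slice, with diagnostics."""

    q: float
    tau: float  # ps
    alpha: float  # dimensionless, in [0, 1)
    chi0: float  # same units as chi''
    resid: float = np.nan  # relative weighted residual norm
    converged: bool = True
    cov: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must lie in [0, 1)")
        if not self.chi0 > 0:
            raise ValueError("chi0 must be positive")


def bose_factor(frequency, temperature):
    """Bose occupation n_B(nu) = 1 / (exp(h nu / k_B T) - 1).

    ``frequency`` in THz (scalar or array), ``temperature`` in kelvin.
    """
    frequency = np.asarray(frequency, dtype=float)
    if np.any(frequency <= 0):
        raise ValueError("frequency must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = PLANCK_UEV_PER_THZ * frequency / (BOLTZMANN_UEV_PER_K * temperature)
    out = 1.0 / np.expm1(x)
    return out if out.ndim else float(out)


def to_susceptibility(grid: SpectrumGrid) -> SpectrumGrid:
    """Convert a structure-factor grid to susceptibility: chi'' = S / n_B."""
    if grid.kind != STRUCTURE_FACTOR:
        raise ValueError("grid is already a susceptibility")
    nb = bose_factor(grid.frequencies, grid.temperature)
    intensity = grid.intensity / nb
    error = None if grid.error is None else grid.error / nb
    return replace(grid, intensity=intensity, error=error, kind=SUSCEPTIBILITY)


def cole_cole(frequency, tau: float, alpha: float, chi0: float):
    """Cole-Cole susceptibility at ``frequency`` (THz, scalar or array).

    Symmetric on a log-frequency axis about the peak at 1/(2 pi tau);
    alpha = 0 gives the Debye lineshape chi0 * x / (1 + x^2).
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must lie in [0, 1)")
    if not chi0 > 0:
        raise ValueError("chi0 must be positive")
    frequency = np.asarray(frequency, dtype=float)
    if np.any(frequency <= 0):
        raise ValueError("frequency must be positive")
    xp = (2.0 * np.pi * frequency * tau) ** (1.0 - alpha)
    s = np.sin(np.pi * alpha / 2.0)
    c = np.cos(np.pi * alpha / 2.0)
    out = chi0 * xp * c / (1.0 + 2.0 * xp * s + xp * xp)
    return out if out.ndim else float(out)


def peak_frequency(tau: float) -> float:
    """Peak frequency (THz) of a relaxation with time ``tau`` (ps): 1/(2 pi tau)."""
    if not tau > 0:
        raise ValueError("tau must be positive")
    return 1.0 / (2.0 * np.pi * tau)


def _log_frequency_weights(freq: np.ndarray) -> np.ndarray:
    # Trapezoid measure in ln(nu): makes an arbitrary grid behave like a
    # uniform log-spaced one, so dense linear grids do not dominate the fit.
    ln = np.log(freq)
    w = np.empty_like(ln)
    w[1:-1] = 0.5 * (ln[2:] - ln[:-2])
    w[0] = ln[1] - ln[0]
    w[-1] = ln[-1] - ln[-2]
    return w / w.mean()


def fit_cole_cole(
    grid: SpectrumGrid,
    q_index: int,
    freq_window: tuple[float, float] | None = None,
    max_relative_residual: float = 0.25,
) -> ColeColeParams:
    """Fit the Cole-Cole model to one q slice of a susceptibility grid.

    Weighted least squares: weights are 1/sigma^2 when an error matrix is
    present, otherwise uniform in log-frequency.  Parameters are bounded
    (tau in [1e-3, 1e6] ps, alpha in [0, 0.99], chi0 > 0); the initial tau
    comes from the grid argmax via tau0 = 1/(2 pi nu_max) and three alpha
    starts are tried, keeping the best.  ``converged`` is False when the
    relative residual norm exceeds ``max_relative_residual`` or the solution
    sits at the tau bounds or the alpha upper bound (alpha = 0, the Debye
    limit, is a legitimate interior physical answer and is not flagged).
    """
    if grid.kind != SUSCEPTIBILITY:
        raise ValueError("fit_cole_cole requires a susceptibility grid")
    freq, y, err = grid.slice(q_index)
    if freq_window is not None:
        lo, hi = freq_window
        keep = (freq >= lo) & (freq <= hi)
        freq, y = freq[keep], y[keep]
        err = None if err is None else err[keep]
    if freq.size < 8:
        raise ValueError("need at least 8 frequency points to fit")
    if not np.any(y > 0):
        raise ValueError("all-zero (or non-positive) slice cannot be fitted")

    if err is not None and np.all(err > 0):
        w = 1.0 / err**2
    else:
        w = _log_frequency_weights(freq)
    sw = np.sqrt(w)

    imax = int(np.argmax(y))
    peak_h = float(y[imax])
    tau0 = float(np.clip(1.0 / (2.0 * np.pi * freq[imax]), *TAU_BOUNDS))
    chi00 = 2.0 * peak_h

    lb = np.array([np.log(TAU_BOUNDS[0]), ALPHA_BOUNDS[0], 1e-12])
    ub = np.array([np.log(TAU_BOUNDS[1]), ALPHA_BOUNDS[1], np.inf])

    def residuals(p):
        ltau, alpha, chi0 = p
        return sw * (cole_cole(freq, float(np.exp(ltau)), alpha, chi0) - y)

    best = None
    for a0 in _ALPHA_STARTS:
        x0 = np.array([np.log(tau0), a0, chi00])
        sol = least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol

    ltau, alpha, chi0 = best.x
    tau = float(np.exp(ltau))
    rel_resid = float(np.linalg.norm(best.fun) / np.linalg.norm(sw * y))

    at_bound = (
        tau <= TAU_BOUNDS[0] * (1 + 1e-9)
        or tau >= TAU_BOUNDS[1] * (1 - 1e-9)
        or alpha >= ALPHA_BOUNDS[1] - 1e-9
    )
    converged = bool(best.success and not at_bound and rel_resid <= max_relative_residual)

    cov = None
    try:  # Gauss-Newton covariance in (ln tau, alpha, chi0); best effort
        jtj = best.jac.T @ best.jac
        dof = max(freq.size - 3, 1)
        cov = np.linalg.inv(jtj) * 2.0 * best.cost / dof
    except np.linalg.LinAlgError:
        pass

    return ColeColeParams(
        q=float(grid.q_values[q_index]),
        tau=tau,
        alpha=float(alpha),
        chi0=float(chi0),
        resid=rel_resid,
        converged=converged,
        cov=cov,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O

def write_spectrum(grid: SpectrumGrid, path: str | Path) -> None:
    """Write a grid as delimited text: q, frequency, intensity, error."""
    nq, nf = grid.intensity.shape
    err = grid.error if grid.error is not None else np.zeros_like(grid.intensity)
    df = pd.DataFrame(
        {
            "q": np.repeat(grid.q_values, nf),
            "frequency": np.tile(grid.frequencies, nq),
            "intensity": grid.intensity.ravel(),
            "error": err.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_spectrum(
    grid_path: str | Path,
    temperature: float = 280.0,
    kind: str = SUSCEPTIBILITY,
    energy_units: str = "THz",
) -> SpectrumGrid:
    """Read a delimited spectrum written by :func:`write_spectrum`.

    ``energy_units="ueV"`` accepts a grid whose frequency column is an
    energy transfer in microelectronvolt; it is converted via nu = E / h.
    """
    df = pd.read_csv(grid_path, sep=None, engine="python")
    required = {"q", "frequency", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"spectrum file must have columns {sorted(required)}")
    if energy_units == "ueV":
        df = df.assign(frequency=df["frequency"] / PLANCK_UEV_PER_THZ)
    elif energy_units != "THz":
        raise ValueError("energy_units must be 'THz' or 'ueV'")
    q_values = np.unique(df["q"].to_numpy())
    frequencies = np.unique(df["frequency"].to_numpy())
    pivot = df.pivot_table(index="q", columns="frequency", values="intensity")
    intensity = pivot.to_numpy()
    error = None
    if "error" in df.columns and (df["error"] > 0).any():
        error = df.pivot_table(index="q", columns="frequency", values="error").to_numpy()
    return SpectrumGrid(
        q_values=q_values,
        frequencies=frequencies,
        intensity=intensity,
        error=error,
        temperature=temperature,
        kind=kind,
    )


def fits_to_frame(fits: list[ColeColeParams]) -> pd.DataFrame:
    """Tabulate fitted parameters: q, tau_ps, alpha, chi0, resid, converged."""
    return pd.DataFrame(
        {
            "q": [f.q for f in fits],
            "tau_ps": [f.tau for f in fits],
            "alpha": [f.alpha for f in fits],
            "chi0": [f.chi0 for f in fits],
            "resid": [f.resid for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
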