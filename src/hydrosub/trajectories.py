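"""Particle trajectory container and delimited-text I/O.

Trajectories are stored dense: one common observation-time grid and a
``(n_particles, n_times, n_dims)`` coordinate array in Angstrom.  Files use
the long format ``time  particle_id  x  y  z`` with unused dimensions
written as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "read_trajectory", "write_trajectory"]


@dataclass
class Trajectory:
    """Time-ordered coordinates for an ensemble of particles.

    times : (nt,) ps, strictly increasing.
    positions : (n_particles, nt, dims) Angstrom, dims in {1, 2, 3}.
    """

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must be (n_particles, n_times, dims)")
        if self.positions.shape[1] != self.times.size:
            raise ValueError("time axis length mismatch")
        if self.positions.shape[2] not in (1, 2, 3):
            raise ValueError("dims must be 1, 2 or 3")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def dims(self) -> int:
        return self.positions.shape[2]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def lateral(self) -> "Trajectory":
        """Drop the last (surface-normal) coordinate.

        Near a confining surface the normal coordinate saturates, so
        in-plane displacement is the meaningful measure of translational
        mobility.
        """
        if self.dims < 2:
            raise ValueError("lateral projection needs at least 2 dimensions")
        return Trajectory(times=self.times, positions=self.positions[:, :, :-1])


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    n, nt, d = traj.positions.shape
    xyz = np.zeros((n, nt, 3))
    xyz[:, :, :d] = traj.positions
    df = pd.DataFrame(
        {
            "time": np.tile(traj.times, n),
            "particle_id": np.repeat(np.arange(n), nt),
            "x": xyz[:, :, 0].ravel(),
            "y": xyz[:, :, 1].ravel(),
            "z": xyz[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_trajectory(path: str | Path, dims: int = 3) -> Trajectory:
    """Read the long-format table; all particles must share one time grid."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"time", "particle_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory file must have columns {sorted(required)}")
    df = df.sort_values(["particle_id", "time"], kind="stable")
    times = np.unique(df["time"].to_numpy())
    ids = np.unique(df["particle_id"].to_numpy())
    if len(df) != times.size * ids.size:
        raise ValueError("particles do not share a common time grid")
    coords = df[["x", "y", "z"]].to_numpy().reshape(ids.size, times.size, 3)
    return Trajectory(times=times, positions=coords[:, :, :dims])
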