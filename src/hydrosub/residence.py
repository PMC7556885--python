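"""Residence times: first passage to a displacement threshold.

The microscopic mobility of a water molecule is summarised by its residence
time tau_res: the time needed to move a threshold distance (default 3.5
Angstrom, the radius of water's first coordination shell).  Extraction is
sequential first passage with reset: starting from a reference position,
the first frame at which the Euclidean displacement reaches the threshold
closes one residence interval; the reference is then moved to the current
position and the scan continues.  The final, unfinished interval of each
particle is censored: counted but excluded from the samples, since keeping
it would bias the distribution tail.

Distributions are log-binned probability mass functions; the second moment
<(tau_res - <tau_res>)^2> quantifies mobility heterogeneity.  Near a planar
surface at z = 0, residence statistics can be resolved by hydration layer
(3.5 Angstrom slabs indexed outward from the surface); a residence interval
belongs to the layer of its starting frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectories import Trajectory

__all__ = [
    "ResidenceTimeSet",
    "ResidenceDistribution",
    "residence_times",
    "residence_distribution",
    "second_moment",
    "assign_layers",
    "layer_residence_distributions",
]

DEFAULT_THRESHOLD = 3.5  # Angstrom, first coordination shell of water
DEFAULT_LAYER_THICKNESS = 3.5  # Angstrom per hydration layer


@dataclass
class ResidenceTimeSet:
    """Completed residence intervals plus censoring metadata.

    samples : (n,) residence times in ps, all positive.
    censored_count : unfinished final intervals (one per particle that
        had any dwell left at the end of the trajectory).
    threshold : displacement threshold in Angstrom.
    layers : optional per-sample hydration-layer label (1-based).
    """

    samples: np.ndarray
    censored_count: int = 0
    threshold: float = DEFAULT_THRESHOLD
    layers: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples <= 0):
            raise ValueError("residence samples must be positive")
        if self.censored_count < 0:
            raise ValueError("censored_count must be non-negative")
        if self.layers is not None:
            self.layers = np.asarray(self.layers, dtype=int)
            if self.layers.shape != self.samples.shape:
                raise ValueError("layers must align with samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def censored_fraction(self) -> float:
        total = self.n + self.censored_count
        return self.censored_count / total if total else 0.0


@dataclass
class ResidenceDistribution:
    """Log-binned probability mass function of residence times.

    edges : (nbins + 1,) strictly increasing bin edges in ps.
    mass : (nbins,) probability mass per bin, summing to 1.
    count : total number of samples behind the histogram.
    """

    edges: np.ndarray
    mass: np.ndarray
    count: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.size != self.edges.size - 1:
            raise ValueError("need one more edge than bins")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if self.count > 0 and abs(self.mass.sum() - 1.0) > 1e-12:
            raise ValueError("probability masses must sum to 1")

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers (natural for log-spaced bins)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def density(self) -> np.ndarray:
        """Probability density per bin: mass / width."""
        return self.mass / self.widths

    def mean(self) -> float:
        """Mean of the binned distribution (log-uniform within bins)."""
        # log-uniform within [a, b] has mean (b - a)/ln(b/a)
        a, b = self.edges[:-1], self.edges[1:]
        return float(np.sum(self.mass * (b - a) / np.log(b / a)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_lo": self.edges[:-1], "bin_hi": self.edges[1:], "mass": self.mass}
        )


def _first_passage_indices(
    pos: np.ndarray, times: np.ndarray, threshold: float
) -> tuple[list[float], list[int], bool]:
    """Sequential-reset first passage for one particle.

    Returns (durations, start_indices, censored).  Scans in geometrically
    growing chunks so a fast particle with many short intervals stays
    linear in trajectory length.
    """
    th2 = threshold * threshold
    nt = pos.shape[0]
    durations: list[float] = []
    starts: list[int] = []
    i = 0
    while i < nt - 1:
        ref = pos[i]
        j = -1
        lo, chunk = i + 1, 32
        while lo < nt:
            hi = min(nt, lo + chunk)
            d2 = ((pos[lo:hi] - ref) ** 2).sum(axis=1)
            hit = np.nonzero(d2 >= th2)[0]
            if hit.size:
                j = lo + int(hit[0])
                break
            lo, chunk = hi, chunk * 2
        if j < 0:
            return durations, starts, True  # censored tail interval
        durations.append(float(times[j] - times[i]))
        starts.append(i)
        i = j
    # reference reached the final frame exactly: nothing left to censor
    return durations, starts, False


def residence_times(traj: Trajectory, threshold: float = DEFAULT_THRESHOLD) -> ResidenceTimeSet:
    """Extract residence-time samples from every particle of a trajectory.

    Each sample is the elapsed time from a reference frame to the first
    frame whose Euclidean displacement from the reference is >= threshold
    (no interpolation between frames); the reference then resets there.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if traj.n_frames < 2:
        raise ValueError("need at least two frames to measure residence times")
    samples: list[float] = []
    censored = 0
    for p in range(traj.n_particles):
        durations, _, was_censored = _first_passage_indices(
            traj.positions[p], traj.times, threshold
        )
        samples.extend(durations)
        censored += int(was_censored)
    return ResidenceTimeSet(
        samples=np.asarray(samples, dtype=float),
        censored_count=censored,
        threshold=threshold,
    )


def residence_distribution(
    rts: ResidenceTimeSet, bins_per_decade: int = 10
) -> ResidenceDistribution:
    """Log-binned probability mass function spanning [min, max] samples."""
    if rts.n < 1:
        raise ValueError("no residence samples to bin")
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    lo, hi = float(rts.samples.min()), float(rts.samples.max())
    if hi / lo < 1.0 + 1e-9:  # all samples (essentially) equal
        lo, hi = lo / 1.05, hi * 1.05
        edges = np.array([lo, hi])
    else:
        nbins = max(1, int(np.ceil(np.log10(hi / lo) * bins_per_decade)))
        edges = np.geomspace(lo, hi, nbins + 1)
    counts, edges = np.histogram(rts.samples, bins=edges)
    return ResidenceDistribution(edges=edges, mass=counts / rts.n, count=rts.n)


def second_moment(rts: ResidenceTimeSet) -> tuple[float, float]:
    """Sample mean and mean squared deviation sum((t - tbar)^2) / N."""
    if rts.n < 2:
        raise ValueError("need at least two samples")
    mean = float(rts.samples.mean())
    msd_dev = float(np.mean((rts.samples - mean) ** 2))
    return mean, msd_dev


def assign_layers(
    traj: Trajectory, layer_thickness: float = DEFAULT_LAYER_THICKNESS
) -> np.ndarray:
    """Per-frame hydration-layer labels above the plane z = 0.

    The surface-normal coordinate is the last axis of the trajectory.
    Layer index is 1-based: floor(z / thickness) + 1, so z in [0, 3.5)
    is layer 1, [3.5, 7) layer 2, and so on.
    """
    if layer_thickness <= 0:
        raise ValueError("layer_thickness must be positive")
    z = traj.positions[:, :, -1]
    if np.any(z < 0):
        raise ValueError("coordinates below the surface plane (z < 0)")
    return np.floor(z / layer_thickness).astype(int) + 1


def layer_residence_distributions(
    traj: Trajectory,
    threshold: float = DEFAULT_THRESHOLD,
    layer_thickness: float = DEFAULT_LAYER_THICKNESS,
    bins_per_decade: int = 10,
) -> dict[int, ResidenceDistribution]:
    """Residence distributions grouped by the layer of each interval's start.

    Layers with no completed interval are omitted from the map.
    """
    labels = assign_layers(traj, layer_thickness)
    per_layer: dict[int, list[float]] = {}
    for p in range(traj.n_particles):
        durations, starts, _ = _first_passage_indices(
            traj.positions[p], traj.times, threshold
        )
        for dur, s in zip(durations, starts):
            per_layer.setdefault(int(labels[p, s]), []).append(dur)
    out: dict[int, ResidenceDistribution] = {}
    for layer in sorted(per_layer):
        rts = ResidenceTimeSet(
            samples=np.asarray(per_layer[layer]), threshold=threshold
        )
        out[layer] = residence_distribution(rts, bins_per_decade)
    return out
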