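"""Core data containers shared across the package.

Conventions: spike times are stored in seconds, bin widths are expressed in
milliseconds at every interface, and time bins are half-open intervals
``[t*dt, (t+1)*dt)`` with 0-based indices.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "SpikeRaster",
    "BinnedActivity",
    "BranchingParams",
    "NetworkRun",
]


@dataclass
class SpikeRaster:
    """Spike times of a set of units.

    Parameters
    ----------
    unit_ids : array of int
        Unit label per spike (non-negative integers, not necessarily dense).
    times : array of float
        Spike time per spike, in seconds.
    t_stop : float, optional
        Recording length in seconds.  Defaults to the largest spike time.
    """

    unit_ids: np.ndarray
    times: np.ndarray
    t_stop: Optional[float] = None

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.unit_ids.shape != self.times.shape:
            raise ValueError("unit_ids and times must have equal length")
        if self.times.size and not np.all(np.isfinite(self.times)):
            raise ValueError("spike times must be finite")
        if self.times.size and self.times.min() < 0:
            raise ValueError("spike times must be non-negative")
        if self.unit_ids.size and self.unit_ids.min() < 0:
            raise ValueError("unit ids must be non-negative")
        if self.t_stop is None:
            self.t_stop = float(self.times.max()) if self.times.size else 0.0
        self.t_stop = float(self.t_stop)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def units(self) -> np.ndarray:
        """Sorted array of distinct unit ids present in the raster."""
        return np.unique(self.unit_ids)

    @property
    def n_units(self) -> int:
        return int(self.units.size)

    def unit_times(self, unit: int) -> np.ndarray:
        """Sorted spike times (s) of one unit."""
        return np.sort(self.times[self.unit_ids == unit])

    def restrict(self, units) -> "SpikeRaster":
        """Raster restricted to the given unit ids (order irrelevant)."""
        mask = np.isin(self.unit_ids, np.asarray(units))
        return SpikeRaster(self.unit_ids[mask], self.times[mask], t_stop=self.t_stop)


@dataclass
class BinnedActivity:
    """Population spike counts per time bin.

    ``label`` distinguishes fully sampled network activity from subsampled
    observations; ``n_units`` records how many units contributed (``None`` if
    unknown, e.g. for externally supplied count files).
    """

    counts: np.ndarray
    dt: float  # bin width, ms
    label: str = "subsampled"
    n_units: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.label not in ("full", "subsampled"):
            raise ValueError("label must be 'full' or 'subsampled'")

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def duration_s(self) -> float:
        return self.counts.size * self.dt / 1000.0

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    def per_unit_rate(self) -> float:
        """Mean firing rate per contributing unit in Hz (needs ``n_units``)."""
        if not self.n_units:
            raise ValueError("n_units unknown; cannot compute per-unit rate")
        return self.mean / (self.n_units * self.dt / 1000.0)

    def rebin(self, bin_size: float) -> "BinnedActivity":
        """Aggregate to a coarser bin size (must be a multiple of ``dt``)."""
        factor = bin_size / self.dt
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError(
                f"bin size {bin_size} ms is not a positive multiple of the "
                f"native bin width {self.dt} ms"
            )
        factor = int(round(factor))
        n = (self.counts.size // factor) * factor
        agg = self.counts[:n].reshape(-1, factor).sum(axis=1)
        return BinnedActivity(agg, dt=bin_size, label=self.label, n_units=self.n_units)


@dataclass(frozen=True)
class BranchingParams:
    """Full parameterization of one branching-network simulation."""

    m: float  # branching ratio
    h: float  # mean total external input per bin (spikes/bin)
    N: int = 10_000  # network size
    n: int = 50  # number of sampled units
    kappa: int = 4  # out-degree
    dt: float = 4.0  # bin width, ms
    L: int = 100_000  # number of recorded bins
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("m must be non-negative")
        if self.h < 0:
            raise ValueError("h must be non-negative")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        p = self.m / self.kappa
        if not (0.0 <= p <= 1.0):
            raise ValueError(
                f"per-connection probability p=m/kappa={p:.4g} outside [0, 1]"
            )
        if not (1 <= self.n <= self.N):
            raise ValueError("need 1 <= n <= N")
        if self.kappa > self.N - 1:
            raise ValueError("kappa must not exceed N-1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.L < 1:
            raise ValueError("L must be >= 1")

    @property
    def p(self) -> float:
        """Per-connection activation probability m/kappa."""
        return self.m / self.kappa

    @property
    def tau_bins(self) -> float:
        """Intrinsic timescale in bins, -1/ln(m), for 0 < m < 1."""
        if not (0.0 < self.m < 1.0):
            return float("nan")
        return -1.0 / np.log(self.m)

    @property
    def tau_ms(self) -> float:
        return self.tau_bins * self.dt

    def with_(self, **kwargs) -> "BranchingParams":
        return replace(self, **kwargs)


@dataclass
class NetworkRun:
    """Result of a finite-network simulation.

    The ``n`` sampled units are fixed before the run; their raster uses dense
    unit ids ``0..n-1``.  ``sampled_counts`` is the per-bin sum over exactly
    those units.
    """

    full_counts: BinnedActivity
    sampled_counts: BinnedActivity
    sampled_raster: SpikeRaster
    params: BranchingParams
    saturated_bins: int = 0
    spike_bins: np.ndarray = field(default=None, repr=False)  # bin index per sampled spike

    @property
    def n_available(self) -> int:
        return self.params.n
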