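"""Branching-process and branching-network simulators.

The population-level model evolves the total activity

    A_{t+1} = sum_{i=1}^{A_t} Y_{t,i} + h_t,

with offspring of mean ``m`` per active unit and Poisson immigration of mean
``h`` per bin.  The network-level model maps the same process onto ``N``
neurons with annealed disorder: every active neuron activates each of its
``kappa`` (freshly drawn) postsynaptic partners with probability ``p = m /
kappa``, recurrent targets are drawn without replacement so no neuron is
activated twice by recurrence within a bin, and external input arrives as
Poisson activations of uniformly random neurons.  Observation is restricted
to ``n`` units selected once before the run.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .types import BinnedActivity, BranchingParams, NetworkRun, SpikeRaster

__all__ = [
    "ExplosionError",
    "solve_input_rate",
    "stationary_mean",
    "burn_in_bins",
    "simulate_population",
    "simulate_network",
    "simulate_subsampled_counts",
    "subsample",
]


class ExplosionError(RuntimeError):
    """Raised when simulated activity exceeds the configured cap."""

    def __init__(self, bin_index: int, cap: float):
        self.bin_index = bin_index
        self.cap = cap
        super().__init__(
            f"activity exceeded cap {cap:g} at bin {bin_index} (including burn-in)"
        )


def solve_input_rate(R: float, dt: float, N: int, m: float) -> float:
    """External input per bin matching a target per-neuron rate.

    Parameters
    ----------
    R : float
        Target stationary firing rate per neuron, Hz.
    dt : float
        Bin width, ms.
    N : int
        Network size.
    m : float
        Branching ratio; must satisfy ``m < 1`` for a stationary match.

    Returns
    -------
    float
        ``h = R * dt * N * (1 - m)`` in spikes per bin (dt in seconds).
    """
    if m >= 1:
        raise ValueError("no stationary input rate exists for m >= 1")
    if R <= 0:
        raise ValueError("rate R must be positive")
    if dt <= 0 or N < 1:
        raise ValueError("dt must be positive and N >= 1")
    return R * (dt / 1000.0) * N * (1.0 - m)


def stationary_mean(h: float, m: float) -> float:
    """Stationary mean activity ``h / (1 - m)`` (spikes per bin)."""
    if m >= 1:
        raise ValueError("no stationary mean exists for m >= 1")
    if h < 0:
        raise ValueError("h must be non-negative")
    return h / (1.0 - m)


def burn_in_bins(m: float) -> int:
    """Bins discarded before recording a stationary trace: ceil(10/|ln m|)."""
    if not (0.0 < m < 1.0):
        return 0
    return int(math.ceil(-10.0 / math.log(m)))


def _seeds(seed: int, count: int = 3) -> list:
    state = np.random.SeedSequence(seed).generate_state(count)
    return [int(s) for s in state]


def _input_array(h, L: int, burn: int) -> np.ndarray:
    h_arr = np.asarray(h, dtype=np.float64)
    if h_arr.ndim == 0:
        return np.full(L + burn, float(h_arr))
    if h_arr.size != L:
        raise ValueError("per-bin input array must have length L")
    if burn:
        h_arr = np.concatenate([np.full(burn, h_arr[0]), h_arr])
    return np.ascontiguousarray(h_arr)


def _initial_activity(params: BranchingParams, a0: Optional[int]) -> int:
    if a0 is not None:
        if a0 < 0:
            raise ValueError("initial activity must be non-negative")
        return int(a0)
    if params.m >= 1:
        return 0
    return int(round(stationary_mean(params.h, params.m)))


def simulate_population(
    params: BranchingParams,
    *,
    stationary: bool = True,
    offspring: str = "binomial",
    a0: Optional[int] = None,
    cap: Optional[float] = None,
    h_t: Optional[Sequence[float]] = None,
) -> BinnedActivity:
    """Simulate the population-level branching process with immigration.

    Stationary runs start at ``A_0 = round(h/(1-m))`` and discard a burn-in of
    ``ceil(10*tau)`` bins; ``stationary=False`` records from ``A_0`` (default
    0 for m >= 1) with no burn-in, as needed for avalanche or perturbation
    protocols.

    Parameters
    ----------
    offspring : {"binomial", "poisson"}
        Total-offspring law: Binomial(kappa*A_t, m/kappa) matches the network
        mapping (default); Poisson(m*A_t) is the classic alternative.
    cap : float, optional
        Explosion guard; default ``max(100 * h/(1-m), 10_000)`` for
        stationary runs, ``1e12`` otherwise.

    Raises
    ------
    ValueError
        If a stationary run is requested with m >= 1.
    ExplosionError
        If the activity exceeds ``cap`` (reports the offending bin).
    """
    if offspring not in ("binomial", "poisson"):
        raise ValueError("offspring must be 'binomial' or 'poisson'")
    if stationary and params.m >= 1:
        raise ValueError("stationary run requested but m >= 1 is non-stationary")
    burn = burn_in_bins(params.m) if stationary else 0
    if cap is None:
        cap = (
            max(100.0 * stationary_mean(params.h, params.m), 10_000.0)
            if params.m < 1
            else 1e12
        )
    h_arr = _input_array(params.h if h_t is None else h_t, params.L, burn)
    kseed = _seeds(params.seed, 1)[0]
    counts, exploded = _kernels.population_kernel(
        kseed,
        params.L,
        burn,
        float(params.m),
        h_arr,
        int(params.kappa),
        _initial_activity(params, a0),
        float(cap),
        offspring == "poisson",
    )
    if exploded >= 0:
        raise ExplosionError(exploded, cap)
    return BinnedActivity(counts, dt=params.dt, label="full", n_units=params.N)


def simulate_network(
    params: BranchingParams,
    *,
    stationary: bool = True,
    a0: Optional[int] = None,
    raster: bool = True,
    h_t: Optional[Sequence[float]] = None,
) -> NetworkRun:
    """Simulate the finite annealed-disorder network and sample ``n`` units.

    The sampled unit set is fixed before the run; by neuron exchangeability
    the raster uses dense unit ids ``0..n-1``.  Spike times are placed
    uniformly at random within their bin.  Bins whose requested recurrent
    activations exceeded ``N`` saturate at ``N`` and are counted in
    ``NetworkRun.saturated_bins``.
    """
    if stationary and params.m >= 1:
        raise ValueError("stationary run requested but m >= 1 is non-stationary")
    burn = burn_in_bins(params.m) if stationary else 0
    h_arr = _input_array(params.h if h_t is None else h_t, params.L, burn)
    dyn_seed, id_seed, jitter_seed = _seeds(params.seed, 3)
    full, samp, saturated = _kernels.network_kernel(
        dyn_seed,
        params.L,
        burn,
        float(params.m),
        h_arr,
        int(params.kappa),
        int(params.N),
        int(params.n),
        _initial_activity(params, a0),
    )
    full_act = BinnedActivity(full, dt=params.dt, label="full", n_units=params.N)
    samp_act = BinnedActivity(samp, dt=params.dt, label="subsampled", n_units=params.n)
    t_stop = params.L * params.dt / 1000.0
    spike_bins = None
    if raster:
        unit_ids, spike_bins = _kernels.assign_unit_ids(id_seed, samp, int(params.n))
        jitter = np.random.default_rng(jitter_seed).random(unit_ids.size)
        times = (spike_bins + jitter) * (params.dt / 1000.0)
        sampled_raster = SpikeRaster(unit_ids, times, t_stop=t_stop)
    else:
        sampled_raster = SpikeRaster(
            np.empty(0, np.int64), np.empty(0, np.float64), t_stop=t_stop
        )
    return NetworkRun(
        full_counts=full_act,
        sampled_counts=samp_act,
        sampled_raster=sampled_raster,
        params=params,
        saturated_bins=int(saturated),
        spike_bins=spike_bins,
    )


def simulate_subsampled_counts(
    params: BranchingParams,
    *,
    stationary: bool = True,
    h_t: Optional[Sequence[float]] = None,
    emulate: bool = True,
) -> BinnedActivity:
    """Subsampled per-bin counts of a network run, skipping raster assembly.

    With ``emulate=True`` (default) the full activity evolves by the
    population-level update and the observed counts are drawn per bin as
    Hypergeometric(A_t, N - A_t, n) — exact for the annealed-disorder network
    up to the O(h*m*A/N) rate shift caused by external arrivals colliding
    with recurrently activated neurons, and roughly 4x faster.  Used for
    bootstrap replicates and matched-model surrogates; ``emulate=False``
    defers to the full network simulator.
    """
    if not emulate:
        return simulate_network(
            params, raster=False, stationary=stationary, h_t=h_t
        ).sampled_counts
    full = simulate_population(params, stationary=stationary, h_t=h_t)
    A = np.minimum(full.counts, params.N)
    rng = np.random.default_rng(_seeds(params.seed, 4)[3])
    samp = np.zeros(A.size, dtype=np.int64)
    pos = A > 0
    samp[pos] = rng.hypergeometric(A[pos], params.N - A[pos], params.n)
    return BinnedActivity(samp, dt=params.dt, label="subsampled", n_units=params.n)


def subsample(run: NetworkRun, n_prime: int, seed: int) -> BinnedActivity:
    """Per-bin counts of a fixed random subset of ``n_prime`` sampled units.

    The subset is drawn once, uniformly without replacement, from the run's
    ``n`` recorded units.  ``n_prime`` equal to the number of available units
    reproduces the run's sampled counts exactly.
    """
    n_avail = run.params.n
    if not (1 <= n_prime <= n_avail):
        raise ValueError(f"n_prime must be in [1, {n_avail}]")
    if run.spike_bins is None:
        raise ValueError("run was simulated without a raster; cannot subsample")
    if n_prime == n_avail:
        return BinnedActivity(
            run.sampled_counts.counts.copy(),
            dt=run.params.dt,
            label="subsampled",
            n_units=n_prime,
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_avail, size=n_prime, replace=False)
    mask = np.isin(run.sampled_raster.unit_ids, chosen)
    counts = np.bincount(run.spike_bins[mask], minlength=run.params.L)
    return BinnedActivity(
        counts, dt=run.params.dt, label="subsampled", n_units=n_prime
    )
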