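"""Numba-compiled inner loops for the simulators.

All kernels seed numba's internal ``np.random`` state on entry, so a given
(seed, parameters) pair yields a bit-identical trace regardless of call order.
External input may be supplied as a per-bin mean array ``h_t`` (length
``L + burn``) to support non-stationary drive; stationary runs pass a constant
array.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "population_kernel",
    "network_kernel",
    "assign_unit_ids",
]


@njit(cache=True)
def population_kernel(seed, L, burn, m, h_t, kappa, a0, cap, poisson_offspring):
    """Population-level branching update with immigration.

    Offspring per bin: Binomial(kappa*A_t, m/kappa) (or Poisson(m*A_t));
    immigration: Poisson(h_t).  Returns (counts[L], explosion_bin) where
    explosion_bin is -1 if the cap was never exceeded, else the 0-based bin
    (counting from the start of the burn-in) at which A_t first exceeded cap.
    """
    np.random.seed(seed)
    out = np.zeros(L, np.int64)
    A = a0
    p = m / kappa
    for t in range(L + burn):
        off = 0
        if A > 0 and m > 0.0:
            if poisson_offspring:
                off = np.random.poisson(m * A)
            else:
                off = np.random.binomial(kappa * A, p)
        ext = 0
        h = h_t[t]
        if h > 0.0:
            ext = np.random.poisson(h)
        A = off + ext
        if A > cap:
            return out, t
        if t >= burn:
            out[t - burn] = A
    return out, -1


@njit(cache=True)
def network_kernel(seed, L, burn, m, h_t, kappa, N, n, a0):
    """Annealed-disorder network dynamics, tracking counts only.

    Per bin: each of the A_t active neurons makes kappa Bernoulli(m/kappa)
    activation attempts; the successful recurrent targets form a uniformly
    random set of distinct neurons (drawn without replacement across all
    sources).  External activations are Poisson with mean h_t, each aimed at
    a uniformly random neuron; a neuron counts once per bin however many
    sources hit it.  Because connectivity is redrawn every step, neurons are
    exchangeable, so the update only needs set sizes:

    * B   recurrent targets  — a uniform B-subset of the N neurons,
    * u   distinct external targets among the E Poisson arrivals,
    * overlap of the two ~ Hypergeometric(B, N-B, u),
    * A_{t+1} = B + u - overlap  (bounded by N by construction),
    * sampled count a_{t+1} ~ Hypergeometric(A_{t+1}, N-A_{t+1}, n) for the
      fixed, randomly pre-selected n units.

    Returns (full[L], sampled[L], saturated_bins) where saturated_bins counts
    bins whose requested recurrent activations exceeded N.
    """
    np.random.seed(seed)
    full = np.zeros(L, np.int64)
    samp = np.zeros(L, np.int64)
    touched = np.zeros(N, np.uint8)
    ext_ids = np.empty(N, np.int64)
    A = a0
    p = m / kappa
    saturated = 0
    for t in range(L + burn):
        B = 0
        if A > 0 and m > 0.0:
            B = np.random.binomial(kappa * A, p)
            if B > N:
                B = N
                saturated += 1
        E = 0
        h = h_t[t]
        if h > 0.0:
            E = np.random.poisson(h)
        u = 0
        for _ in range(E):
            idx = np.random.randint(N)
            if touched[idx] == 0:
                touched[idx] = 1
                ext_ids[u] = idx
                u += 1
        for j in range(u):
            touched[ext_ids[j]] = 0
        overlap = 0
        if B > 0 and u > 0:
            if B >= N:
                overlap = u
            else:
                overlap = np.random.hypergeometric(B, N - B, u)
        A = B + u - overlap
        a = 0
        if A > 0:
            if A >= N:
                a = n
            else:
                a = np.random.hypergeometric(A, N - A, n)
        if t >= burn:
            full[t - burn] = A
            samp[t - burn] = a
    return full, samp, saturated


@njit(cache=True)
def assign_unit_ids(seed, sampled_counts, n):
    """Assign distinct unit ids (0..n-1) to the sampled spikes of each bin.

    Under annealed disorder, which of the n sampled units are active in a bin
    is a uniform random subset of the given size, independent across bins.
    Returns (unit_ids, bin_indices) flattened over all sampled spikes, in bin
    order.
    """
    np.random.seed(seed)
    total = 0
    for t in range(sampled_counts.size):
        total += sampled_counts[t]
    units = np.empty(total, np.int64)
    bins = np.empty(total, np.int64)
    perm = np.arange(n)
    pos = 0
    for t in range(sampled_counts.size):
        a = sampled_counts[t]
        if a == 0:
            continue
        # partial Fisher-Yates: first a entries become a uniform a-subset
        for i in range(a):
            j = i + np.random.randint(n - i)
            perm[i], perm[j] = perm[j], perm[i]
            units[pos] = perm[i]
            bins[pos] = t
            pos += 1
    return units, bins
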