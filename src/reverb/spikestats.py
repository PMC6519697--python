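"""Validation statistics for spike rasters and binned activity.

Covers inter-spike-interval statistics, Fano factors across bin sizes,
activity distributions, avalanche detection with a model-likelihood
comparison, pairwise spike-count correlations, and autocorrelation functions
(population and single-unit, with and without the zero-lag value).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import optimize

from .estimation import bin_spikes
from .types import BinnedActivity, SpikeRaster

__all__ = [
    "ISIStatistics",
    "FanoCurve",
    "CorrelationCurve",
    "AutocorrelationCurve",
    "AvalancheSet",
    "isi_statistics",
    "fano_factor",
    "activity_distribution",
    "detect_avalanches",
    "avalanche_model_likelihood",
    "spike_count_correlation",
    "autocorrelation",
]


@dataclass
class ISIStatistics:
    """Per-unit inter-spike intervals and coefficients of variation."""

    cv: Dict[int, float]  # unit -> std(ISI)/mean(ISI)
    isis: Dict[int, np.ndarray] = field(repr=False, default=None)
    excluded_units: List[int] = field(default_factory=list)

    @property
    def pooled_isis(self) -> np.ndarray:
        if not self.isis:
            return np.empty(0)
        return np.concatenate(list(self.isis.values()))

    @property
    def median_cv(self) -> float:
        vals = np.array(list(self.cv.values()))
        return float(np.median(vals)) if vals.size else float("nan")


@dataclass
class FanoCurve:
    bin_sizes: np.ndarray  # ms
    fano: np.ndarray  # median across units for scope="single_unit"
    scope: str  # single_unit | population | full_network
    per_unit: Optional[Dict[int, np.ndarray]] = field(repr=False, default=None)


@dataclass
class CorrelationCurve:
    bin_sizes: np.ndarray  # ms
    mean_rsc: np.ndarray
    n_pairs: np.ndarray


@dataclass
class AutocorrelationCurve:
    lags_ms: np.ndarray
    values: np.ndarray
    zero_lag_included: bool
    tau_fit_ms: float = float("nan")  # exponential fit on lags >= 1
    tau_naive_ms: float = float("nan")  # fit including lag 0 (if requested)


@dataclass
class AvalancheSet:
    """Sizes and durations of contiguous runs of non-empty bins."""

    sizes: np.ndarray  # total spikes per avalanche
    durations: np.ndarray  # bins per avalanche
    dt: float  # ms
    spans_whole_trace: bool = False  # no empty bin found

    @property
    def n_avalanches(self) -> int:
        return int(self.sizes.size)


def isi_statistics(raster: SpikeRaster, min_spikes: int = 2) -> ISIStatistics:
    """Per-unit sorted ISIs (seconds) and CV; units with < 2 spikes excluded."""
    cvs: Dict[int, float] = {}
    isis: Dict[int, np.ndarray] = {}
    excluded: List[int] = []
    for unit in raster.units:
        t = raster.unit_times(int(unit))
        if t.size < max(min_spikes, 2):
            excluded.append(int(unit))
            continue
        d = np.diff(t)
        isis[int(unit)] = d
        cvs[int(unit)] = float(d.std() / d.mean()) if d.mean() > 0 else float("nan")
    return ISIStatistics(cv=cvs, isis=isis, excluded_units=excluded)


def _counts_at(source, bin_size: float) -> np.ndarray:
    if isinstance(source, BinnedActivity):
        return source.rebin(bin_size).counts
    return bin_spikes(source, bin_size).counts


def fano_factor(source, bin_sizes: Sequence[float], scope: str = "population"):
    """Variance-to-mean ratio of non-overlapping window counts per bin size.

    ``scope="single_unit"`` requires a raster and returns the median F across
    units (units with zero mean count at a bin size are excluded there);
    other scopes evaluate the pooled/population trace.  Partial trailing
    windows are dropped by the underlying binning.
    """
    bin_sizes = np.asarray(bin_sizes, dtype=float)
    if scope == "single_unit":
        if not isinstance(source, SpikeRaster):
            raise TypeError("single-unit Fano factors require a SpikeRaster")
        per_unit: Dict[int, np.ndarray] = {
            int(u): np.full(bin_sizes.size, np.nan) for u in source.units
        }
        for j, bs in enumerate(bin_sizes):
            for u in source.units:
                t = source.times[source.unit_ids == u]
                sub = SpikeRaster(np.zeros(t.size, np.int64), t, t_stop=source.t_stop)
                if sub.n_spikes == 0:
                    continue
                c = bin_spikes(sub, bs).counts
                if c.size < 2 or c.mean() == 0:
                    continue
                per_unit[int(u)][j] = c.var() / c.mean()
        stack = np.vstack([v for v in per_unit.values()])
        fano = np.nanmedian(stack, axis=0)
        return FanoCurve(bin_sizes=bin_sizes, fano=fano, scope=scope, per_unit=per_unit)
    fano = np.empty(bin_sizes.size)
    for j, bs in enumerate(bin_sizes):
        c = _counts_at(source, bs)
        if c.size < 10:
            raise ValueError(f"fewer than 10 windows at bin size {bs} ms")
        if c.mean() == 0:
            fano[j] = float("nan")
        else:
            fano[j] = c.var() / c.mean()
    return FanoCurve(bin_sizes=bin_sizes, fano=fano, scope=scope)


def activity_distribution(counts: BinnedActivity, bin_size: Optional[float] = None):
    """Normalized histogram of spikes per bin after optional re-binning.

    Returns ``(values, probabilities)`` over the integer support
    ``0..max(count)``; probabilities sum to 1.
    """
    act = counts if bin_size is None else counts.rebin(bin_size)
    c = act.counts
    if c.size == 0:
        raise ValueError("empty trace")
    hist = np.bincount(c)
    return np.arange(hist.size), hist / hist.sum()


def detect_avalanches(counts: BinnedActivity) -> AvalancheSet:
    """Maximal runs of consecutive non-empty bins, separated by >= 1 empty bin.

    Size is the total spike count of the run, duration its length in bins.
    A trace with no empty bin yields a single avalanche flagged as spanning
    the whole trace.
    """
    c = counts.counts
    occupied = c > 0
    if not occupied.any():
        return AvalancheSet(
            sizes=np.empty(0, np.int64),
            durations=np.empty(0, np.int64),
            dt=counts.dt,
        )
    padded = np.concatenate([[False], occupied, [False]])
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    cum = np.concatenate([[0], np.cumsum(c)])
    sizes = cum[stops] - cum[starts]
    durations = stops - starts
    return AvalancheSet(
        sizes=sizes.astype(np.int64),
        durations=durations.astype(np.int64),
        dt=counts.dt,
        spans_whole_trace=bool(occupied.all()),
    )


def _smoothed_size_distribution(sizes: np.ndarray):
    """Add-one-smoothed size distribution with a fitted geometric tail.

    Probabilities cover 1..s_max from smoothed empirical counts; mass beyond
    s_max follows a geometric tail whose ratio is the MLE of a geometric law
    on the sizes in the top decade [s_max/10, s_max].  The combined measure is
    normalized over 1..infinity, so no observable size ever has zero mass.
    """
    s_max = int(sizes.max())
    hist = np.bincount(sizes, minlength=s_max + 1)[1:].astype(float)  # support 1..s_max
    hist += 1.0  # add-one smoothing on the observed support
    top = sizes[sizes >= max(1, s_max / 10)]
    if top.size >= 2 and top.max() > top.min():
        mean_excess = float(top.mean() - top.min() + 1.0)
        q = 1.0 - 1.0 / mean_excess
    else:
        q = 0.5
    q = float(np.clip(q, 1e-6, 1 - 1e-9))
    body = hist.sum()
    tail_start = hist[-1] * q  # continue the last body mass geometrically
    tail_total = tail_start / (1.0 - q)
    z = body + tail_total
    return hist / z, q, tail_start / z, s_max


def avalanche_model_likelihood(
    data: AvalancheSet, candidates: Dict[str, BinnedActivity]
) -> Dict[str, float]:
    """Log-likelihood of the observed avalanche sizes under candidate models.

    Each candidate trace is reduced to its empirical avalanche-size
    distribution, regularized with add-one smoothing plus a geometric tail so
    that sizes unseen in the candidate simulation contribute a finite floor,
    never ``-inf``.  Returns ``{label: total log-likelihood}``; larger is
    better.
    """
    if data.n_avalanches == 0:
        raise ValueError("no avalanches in the data")
    out: Dict[str, float] = {}
    for label, trace in candidates.items():
        cand = detect_avalanches(trace)
        if cand.n_avalanches == 0:
            out[label] = float("-inf")
            continue
        probs, q, tail_start, s_max = _smoothed_size_distribution(cand.sizes)
        logp = np.empty(data.sizes.size)
        inside = data.sizes <= s_max
        logp[inside] = np.log(probs[data.sizes[inside] - 1])
        excess = data.sizes[~inside] - s_max
        logp[~inside] = np.log(tail_start) + (excess - 1) * np.log(q)
        out[label] = float(logp.sum())
    return out


def spike_count_correlation(
    raster: SpikeRaster, bin_sizes: Sequence[float]
) -> CorrelationCurve:
    """Mean pairwise Pearson correlation of per-unit binned counts.

    Zero-variance units are excluded pair-wise at each bin size.
    """
    units = raster.units
    if units.size < 2:
        raise ValueError("need at least 2 units")
    bin_sizes = np.asarray(bin_sizes, dtype=float)
    mean_rsc = np.empty(bin_sizes.size)
    n_pairs = np.empty(bin_sizes.size, dtype=np.int64)
    for j, bs in enumerate(bin_sizes):
        dt_s = bs / 1000.0
        n_bins = int(math.floor(raster.t_stop / dt_s + 1e-9))
        if n_bins < 10:
            raise ValueError(f"fewer than 10 bins at bin size {bs} ms")
        mat = np.zeros((units.size, n_bins))
        for i, u in enumerate(units):
            t = raster.times[raster.unit_ids == u]
            idx = np.floor(t / dt_s).astype(np.int64)
            idx = idx[idx < n_bins]
            mat[i] = np.bincount(idx, minlength=n_bins)
        keep = mat.std(axis=1) > 0
        mat = mat[keep]
        if mat.shape[0] < 2:
            mean_rsc[j] = float("nan")
            n_pairs[j] = 0
            continue
        corr = np.corrcoef(mat)
        iu = np.triu_indices(mat.shape[0], k=1)
        mean_rsc[j] = float(corr[iu].mean())
        n_pairs[j] = iu[0].size
    return CorrelationCurve(bin_sizes=bin_sizes, mean_rsc=mean_rsc, n_pairs=n_pairs)


def _fit_tau(lags_ms: np.ndarray, values: np.ndarray, dt: float) -> float:
    """Exponential a*exp(-lag/tau) fitted by least squares; returns tau (ms)."""
    pos = values > 0
    if pos.sum() >= 2:
        coef = np.polyfit(lags_ms[pos], np.log(values[pos]), 1)
        tau0 = -1.0 / coef[0] if coef[0] < 0 else 10 * dt
        a0 = float(np.exp(coef[1]))
    else:
        tau0, a0 = 10 * dt, max(float(values[0]), 1e-3)
    tau0 = float(np.clip(tau0, dt / 100, 1e7))

    def resid(theta):
        a, tau = theta
        return a * np.exp(-lags_ms / tau) - values

    res = optimize.least_squares(
        resid,
        x0=np.array([np.clip(a0, 1e-9, 10.0), tau0]),
        bounds=([1e-12, dt / 1000.0], [10.0, 1e9]),
    )
    return float(res.x[1])


def autocorrelation(
    counts: BinnedActivity,
    max_lag: int,
    exclude_zero_lag: bool = True,
    fit: bool = True,
) -> AutocorrelationCurve:
    """Normalized autocorrelation with optional exponential-decay fits.

    The default fit uses lags >= 1 only — under subsampling the zero-lag
    value is inflated and a naive fit through it severely underestimates the
    timescale.  With ``exclude_zero_lag=False`` the returned curve includes
    r_0 = 1 and ``tau_naive_ms`` carries the naive fit for comparison.
    """
    a = counts.counts.astype(np.float64)
    if max_lag >= a.size // 2:
        raise ValueError("max_lag must be below half the trace length")
    mu = a.mean()
    var = a.var()
    if var == 0:
        raise ValueError("degenerate input: constant activity trace")
    d = a - mu
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        acf[k] = np.dot(d[:-k], d[k:]) / a.size / var
    lags_ms = np.arange(max_lag + 1) * counts.dt
    tau_fit = tau_naive = float("nan")
    if fit:
        tau_fit = _fit_tau(lags_ms[1:], acf[1:], counts.dt)
        if not exclude_zero_lag:
            tau_naive = _fit_tau(lags_ms, acf, counts.dt)
    if exclude_zero_lag:
        return AutocorrelationCurve(
            lags_ms=lags_ms[1:],
            values=acf[1:],
            zero_lag_included=False,
            tau_fit_ms=tau_fit,
        )
    return AutocorrelationCurve(
        lags_ms=lags_ms,
        values=acf,
        zero_lag_included=True,
        tau_fit_ms=tau_fit,
        tau_naive_ms=tau_naive,
    )
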