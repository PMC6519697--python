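"""Multistep-regression (MR) estimation of the branching ratio.

The estimator computes, for lags k = 1..k_max, the linear regression slope
r_k of a_{t+k} on a_t, then fits the geometric decay r_k = b * m^k jointly in
(b, m).  Subsampling rescales the slopes by the common factor b but leaves the
decay base m intact, so the fit recovers m even from a small fraction of
units — unlike the conventional lag-1 slope, which is biased towards 0 under
subsampling.  The intrinsic timescale follows as tau = -dt / ln(m).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulation import simulate_subsampled_counts, solve_input_rate, subsample
from .types import BinnedActivity, BranchingParams, NetworkRun, SpikeRaster

__all__ = [
    "RegressionSlopes",
    "MREstimate",
    "ConsistencyReport",
    "ConsistencyChecks",
    "bin_spikes",
    "regression_slopes",
    "fit_exponential",
    "mr_estimate",
    "conventional_estimate",
    "confidence_interval",
    "window_estimates",
    "subsampling_invariance_curve",
    "consistency_tests",
]

M_UPPER = 1.05  # fit boundary; m_hat above 1 is reported but flagged


@dataclass
class RegressionSlopes:
    """Per-lag regression slopes r_k of a_{t+k} on a_t."""

    lags: np.ndarray  # k, in bins (1..k_max)
    slopes: np.ndarray  # r_k
    n_pairs: np.ndarray  # pairs used per lag
    dt: float  # ms

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.lags, "r_k": self.slopes, "n_pairs": self.n_pairs}
        )


@dataclass
class MREstimate:
    """Fitted MR estimate with diagnostics."""

    m_hat: float
    b_hat: float
    tau_hat: float  # ms; NaN unless 0 < m_hat < 1
    dt: float  # ms
    k_max: int
    residuals: np.ndarray = field(repr=False, default=None)
    flags: Dict[str, bool] = field(default_factory=dict)
    ci_m_16_84: Optional[tuple] = None
    ci_m_5_95: Optional[tuple] = None
    ci_tau_16_84: Optional[tuple] = None
    ci_tau_5_95: Optional[tuple] = None

    def to_dict(self) -> dict:
        def _pair(p):
            return None if p is None else [float(p[0]), float(p[1])]

        return {
            "m_hat": float(self.m_hat),
            "b_hat": float(self.b_hat),
            "tau_hat_ms": float(self.tau_hat),
            "dt_ms": float(self.dt),
            "k_max": int(self.k_max),
            "flags": dict(self.flags),
            "ci_m_16_84": _pair(self.ci_m_16_84),
            "ci_m_5_95": _pair(self.ci_m_5_95),
            "ci_tau_16_84": _pair(self.ci_tau_16_84),
            "ci_tau_5_95": _pair(self.ci_tau_5_95),
        }


@dataclass
class ConsistencyReport:
    """Window-wise estimates and the stationarity comparison."""

    window_m: np.ndarray  # m_hat per window (NaN where the fit failed)
    model_window_m: np.ndarray  # same procedure on the matched model
    variability_p: float  # Levene test p-value, data vs model windows
    window_s: float
    fit_quality: Dict[str, float]
    passed: bool


@dataclass
class ConsistencyChecks:
    """Battery of stationarity / model-adequacy checks."""

    fit_adequacy: bool
    stationarity: bool
    no_trend: bool
    details: Dict[str, float]

    @property
    def passed(self) -> bool:
        return self.fit_adequacy and self.stationarity and self.no_trend

    def to_dict(self) -> dict:
        return {
            "fit_adequacy": bool(self.fit_adequacy),
            "stationarity": bool(self.stationarity),
            "no_trend": bool(self.no_trend),
            "passed": bool(self.passed),
            "details": {k: float(v) for k, v in self.details.items()},
        }


def bin_spikes(raster: SpikeRaster, dt: float) -> BinnedActivity:
    """Pool all units into one train of population spike counts.

    Bins are half-open ``[t*dt, (t+1)*dt)``; the trailing partial bin (beyond
    ``floor(t_stop / dt)`` whole bins) is dropped.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if raster.n_spikes == 0:
        raise ValueError("empty raster")
    dt_s = dt / 1000.0
    n_bins = int(math.floor(raster.t_stop / dt_s + 1e-9))
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    idx = np.floor(raster.times / dt_s).astype(np.int64)
    keep = idx < n_bins
    counts = np.bincount(idx[keep], minlength=n_bins)
    return BinnedActivity(counts, dt=dt, label="subsampled", n_units=raster.n_units)


def regression_slopes(activity: BinnedActivity, k_max: int) -> RegressionSlopes:
    """OLS slope of a_{t+k} on a_t for each lag k = 1..k_max.

    All valid pairs from the full trace are used; means are re-estimated per
    lag from the pairs actually entering that lag's regression.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2 for a subsequent exponential fit")
    a = activity.counts.astype(np.float64)
    L = a.size
    if L <= k_max + 1:
        raise ValueError("trace too short for the requested k_max")
    if np.ptp(a) == 0:
        raise ValueError("degenerate input: constant activity trace")
    lags = np.arange(1, k_max + 1)
    slopes = np.empty(k_max)
    n_pairs = np.empty(k_max, dtype=np.int64)
    for i, k in enumerate(lags):
        x = a[:-k]
        y = a[k:]
        mx = x.mean()
        my = y.mean()
        varx = x.dot(x) / x.size - mx * mx
        if varx <= 0:
            raise ValueError(f"zero variance among the pairs at lag {k}")
        cov = x.dot(y) / x.size - mx * my
        slopes[i] = cov / varx
        n_pairs[i] = x.size
    return RegressionSlopes(lags=lags, slopes=slopes, n_pairs=n_pairs, dt=activity.dt)


def _geometric_residuals(theta, k, r):
    b, m = theta
    return b * m**k - r


def _loglinear_init(k, r):
    pos = r > 0
    if pos.sum() >= 2:
        coef = np.polyfit(k[pos], np.log(r[pos]), 1)
        m0 = float(np.exp(coef[0]))
        b0 = float(np.exp(coef[1]))
        return np.clip(b0, 1e-6, 9.9), np.clip(m0, 1e-6, M_UPPER - 1e-6)
    return None


def fit_exponential(slopes: RegressionSlopes) -> MREstimate:
    """Least-squares fit of r_k = b * m^k jointly in (b, m).

    Multi-start: the initial m comes from a log-linear regression on the
    positive slopes, with fallbacks at m in {0.5, 0.9, 0.99}.  Negative slopes
    at large lags are retained (truncating them biases m upward).  m is
    constrained to (0, 1.05); estimates above 1 are flagged, not rejected.
    """
    k = slopes.lags.astype(np.float64)
    r = slopes.slopes
    if k.size < 2:
        raise ValueError("need at least 2 lags to fit the exponential")
    starts = []
    init = _loglinear_init(k, r)
    if init is not None:
        starts.append(init)
    r1 = r[0]
    for m0 in (0.5, 0.9, 0.99):
        b0 = r1 / m0 if np.isfinite(r1) and abs(r1 / m0) > 1e-12 else 1.0
        starts.append((np.clip(b0, -9.9, 9.9), m0))
    best = None
    for b0, m0 in starts:
        res = optimize.least_squares(
            _geometric_residuals,
            x0=np.array([b0, m0]),
            args=(k, r),
            bounds=([-10.0, 1e-12], [10.0, M_UPPER]),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("exponential fit failed to converge from any start")
    b_hat, m_hat = float(best.x[0]), float(best.x[1])
    tau = -slopes.dt / math.log(m_hat) if 0.0 < m_hat < 1.0 else float("nan")
    flags = {
        "m_at_boundary": bool(m_hat >= M_UPPER - 1e-9 or m_hat <= 1e-9),
        "nonstationary": bool(m_hat >= 1.0),
        "b_above_one": bool(b_hat > 1.0),
    }
    return MREstimate(
        m_hat=m_hat,
        b_hat=b_hat,
        tau_hat=tau,
        dt=slopes.dt,
        k_max=int(slopes.lags[-1]),
        residuals=best.fun,
        flags=flags,
    )


def mr_estimate(activity: BinnedActivity, k_max: int) -> MREstimate:
    """Convenience: regression slopes followed by the exponential fit."""
    return fit_exponential(regression_slopes(activity, k_max))


def conventional_estimate(activity: BinnedActivity) -> float:
    """Classical full-sampling estimator: the lag-1 regression slope.

    Unbiased when the whole population is observed, strongly biased towards 0
    under subsampling.
    """
    return float(regression_slopes(activity, 2).slopes[0])


def confidence_interval(
    estimate: MREstimate,
    params: BranchingParams,
    B: int = 100,
    seed: int = 0,
) -> dict:
    """Parametric-bootstrap confidence intervals for m_hat and tau_hat.

    Simulates ``B`` realizations of the matched model (``params`` should carry
    m = m_hat, the matched rate/n, and L equal to the observed trace length),
    re-estimates m on each, and returns 16-84% and 5-95% quantile intervals.
    The intervals are also written onto ``estimate`` in place.

    Raises
    ------
    RuntimeError
        If more than 20% of the replicates fail to fit.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    child_seeds = np.random.SeedSequence(seed).generate_state(B)
    reps = []
    failed = 0
    for s in child_seeds:
        counts = simulate_subsampled_counts(params.with_(seed=int(s)))
        try:
            est = mr_estimate(counts, estimate.k_max)
            reps.append(est.m_hat)
        except (ValueError, RuntimeError):
            failed += 1
    if failed > 0.2 * B:
        raise RuntimeError(f"{failed}/{B} bootstrap replicates failed to fit")
    reps = np.asarray(reps)
    q = np.quantile(reps, [0.16, 0.84, 0.05, 0.95])
    estimate.ci_m_16_84 = (float(q[0]), float(q[1]))
    estimate.ci_m_5_95 = (float(q[2]), float(q[3]))

    def _tau(m):
        return -estimate.dt / math.log(m) if 0 < m < 1 else float("nan")

    estimate.ci_tau_16_84 = (_tau(q[1]), _tau(q[0]))
    estimate.ci_tau_5_95 = (_tau(q[3]), _tau(q[2]))
    return {
        "m_16_84": estimate.ci_m_16_84,
        "m_5_95": estimate.ci_m_5_95,
        "tau_16_84": estimate.ci_tau_16_84,
        "tau_5_95": estimate.ci_tau_5_95,
        "replicates": reps,
        "n_failed": failed,
    }


def _matched_params(
    activity: BinnedActivity, m: float, N: int = 10_000, seed: int = 0
) -> BranchingParams:
    """Matched-model parameters reproducing the trace's rate, n, and length."""
    if not activity.n_units:
        raise ValueError("matched model requires the trace's n_units")
    R = activity.per_unit_rate()
    h = solve_input_rate(R, activity.dt, N, m)
    return BranchingParams(
        m=m,
        h=h,
        N=N,
        n=activity.n_units,
        dt=activity.dt,
        L=len(activity),
        seed=seed,
    )


def _windowed_m(activity: BinnedActivity, window_bins: int, k_max: int) -> np.ndarray:
    n_win = len(activity) // window_bins
    out = np.full(n_win, np.nan)
    for w in range(n_win):
        seg = activity.counts[w * window_bins : (w + 1) * window_bins]
        try:
            est = mr_estimate(
                BinnedActivity(seg, dt=activity.dt, n_units=activity.n_units),
                k_max,
            )
            out[w] = est.m_hat
        except (ValueError, RuntimeError):
            pass
    return out


def window_estimates(
    activity: BinnedActivity,
    window: float,
    k_max: Optional[int] = None,
    *,
    matched: Optional[BranchingParams] = None,
    N: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ConsistencyReport:
    """MR estimates on non-overlapping windows plus a stationarity test.

    Splits the trace into ``floor(T / window)`` windows (``window`` in
    seconds), estimates m per window, runs the same windowed procedure on a
    matched stationary model, and compares the two sets of window estimates
    with a Levene variance-equality test.
    """
    window_bins = int(round(window * 1000.0 / activity.dt))
    if window_bins < 100:
        raise ValueError("window must span at least 100 bins")
    n_win = len(activity) // window_bins
    if n_win < 2:
        raise ValueError("trace too short: fewer than 2 windows")
    if k_max is None:
        k_max = max(2, min(150, window_bins // 4))
    window_m = _windowed_m(activity, window_bins, k_max)

    if matched is None:
        global_m = float(np.clip(mr_estimate(activity, k_max).m_hat, 1e-6, 0.9999))
        matched = _matched_params(activity, global_m, N=N, seed=seed)
    model_counts = simulate_subsampled_counts(matched.with_(seed=seed))
    model_m = _windowed_m(model_counts, window_bins, k_max)

    data_ok = window_m[np.isfinite(window_m)]
    model_ok = model_m[np.isfinite(model_m)]
    if data_ok.size >= 2 and model_ok.size >= 2:
        p = float(stats.levene(data_ok, model_ok).pvalue)
    else:
        p = float("nan")
    fit_quality = {
        "fraction_windows_fitted": float(data_ok.size / max(n_win, 1)),
        "n_windows": float(n_win),
    }
    passed = bool(
        np.isfinite(p) and p > alpha and fit_quality["fraction_windows_fitted"] >= 0.8
    )
    return ConsistencyReport(
        window_m=window_m,
        model_window_m=model_m,
        variability_p=p,
        window_s=window,
        fit_quality=fit_quality,
        passed=passed,
    )


def subsampling_invariance_curve(
    run: NetworkRun,
    subset_sizes: Sequence[int],
    repeats: int = 20,
    k_max: int = 150,
    seed: int = 0,
) -> pd.DataFrame:
    """Median and 16-84% spread of m_hat over repeated fixed subsets.

    For each requested subset size n', draws ``repeats`` independent fixed
    subsets of the run's sampled units, estimates m on each subset's counts,
    and summarizes the distribution of estimates.
    """
    child = np.random.SeedSequence(seed).generate_state(len(subset_sizes) * repeats)
    rows = []
    i = 0
    for n_prime in subset_sizes:
        estimates = []
        for _ in range(repeats):
            counts = subsample(run, n_prime, int(child[i]))
            i += 1
            try:
                estimates.append(mr_estimate(counts, k_max).m_hat)
            except (ValueError, RuntimeError):
                estimates.append(np.nan)
        est = np.asarray(estimates)
        ok = est[np.isfinite(est)]
        rows.append(
            {
                "n_prime": n_prime,
                "median_m": float(np.median(ok)) if ok.size else np.nan,
                "q16": float(np.quantile(ok, 0.16)) if ok.size else np.nan,
                "q84": float(np.quantile(ok, 0.84)) if ok.size else np.nan,
                "n_ok": int(ok.size),
            }
        )
    return pd.DataFrame(rows)


# --- consistency battery -----------------------------------------------------


def _bic(sse: float, n: int, n_params: int) -> float:
    sse = max(sse, 1e-300)
    return n * math.log(sse / n) + n_params * math.log(n)


def _fit_candidates(slopes: RegressionSlopes) -> Dict[str, float]:
    """BIC of alternative decay models for the slope curve r_k."""
    k = slopes.lags.astype(np.float64)
    r = slopes.slopes
    n = k.size
    out = {}
    exp_fit = fit_exponential(slopes)
    out["exponential"] = _bic(float(np.sum(exp_fit.residuals**2)), n, 2)

    def _offset_resid(theta):
        b, m, c = theta
        return b * m**k + c - r

    res = optimize.least_squares(
        _offset_resid,
        x0=np.array([exp_fit.b_hat, min(max(exp_fit.m_hat, 1e-6), M_UPPER - 1e-6), 0.0]),
        bounds=([-10, 1e-12, -1], [10, M_UPPER, 1]),
    )
    out["exponential_offset"] = _bic(float(np.sum(res.fun**2)), n, 3)
    out["constant"] = _bic(float(np.sum((r - r.mean()) ** 2)), n, 1)

    def _power_resid(theta):
        b, alpha = theta
        return b * k ** (-alpha) - r

    pos = r > 0
    if pos.sum() >= 2:
        coef = np.polyfit(np.log(k[pos]), np.log(r[pos]), 1)
        x0 = np.array([np.clip(np.exp(coef[1]), 1e-6, 9.9), np.clip(-coef[0], 0.0, 9.9)])
    else:
        x0 = np.array([max(r[0], 1e-3), 1.0])
    res = optimize.least_squares(
        _power_resid, x0=x0, bounds=([-10, 0.0], [10, 10.0])
    )
    out["power_law"] = _bic(float(np.sum(res.fun**2)), n, 2)
    return out


def consistency_tests(
    activity: BinnedActivity,
    k_max: Optional[int] = None,
    *,
    window: float = 5.0,
    N: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ConsistencyChecks:
    """Battery of three conservative checks on a binned trace.

    (a) fit adequacy: among exponential, exponential-plus-offset, constant,
        and power-law fits of r_k, an exponential-family model must achieve
        the lowest BIC;
    (b) window stationarity: Levene variance comparison of window-wise m
        estimates against a matched stationary model;
    (c) trend: Spearman rank test of window mean rates against window index
        must be non-significant.
    """
    if k_max is None:
        k_max = max(2, min(150, (len(activity) - 2) // 4))
    slopes = regression_slopes(activity, k_max)
    bics = _fit_candidates(slopes)
    winner = min(bics, key=bics.get)
    fit_ok = winner in ("exponential", "exponential_offset")

    window_bins = int(round(window * 1000.0 / activity.dt))
    n_win = len(activity) // window_bins
    details: Dict[str, float] = {f"bic_{k}": v for k, v in bics.items()}
    details["n_windows"] = float(n_win)

    stat_ok = True
    if n_win >= 2 and activity.n_units:
        try:
            report = window_estimates(
                activity, window, min(k_max, window_bins // 4), N=N, seed=seed
            )
            stat_ok = bool(
                not np.isfinite(report.variability_p)
                or report.variability_p > alpha
            )
            details["levene_p"] = report.variability_p
        except (ValueError, RuntimeError):
            details["levene_p"] = float("nan")

    trend_ok = True
    if n_win >= 3:
        rates = (
            activity.counts[: n_win * window_bins]
            .reshape(n_win, window_bins)
            .mean(axis=1)
        )
        rho, p = stats.spearmanr(np.arange(n_win), rates)
        details["trend_rho"] = float(rho)
        details["trend_p"] = float(p)
        trend_ok = bool(p > alpha)

    return ConsistencyChecks(
        fit_adequacy=fit_ok,
        stationarity=stat_ok,
        no_trend=trend_ok,
        details=details,
    )
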