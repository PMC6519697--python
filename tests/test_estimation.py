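import numpy as np
import pytest
from scipy import stats

from reverb.estimation import (
    RegressionSlopes,
    _fit_candidates,
    bin_spikes,
    confidence_interval,
    consistency_tests,
    conventional_estimate,
    fit_exponential,
    mr_estimate,
    regression_slopes,
    subsampling_invariance_curve,
    window_estimates,
)
from reverb.simulation import simulate_subsampled_counts, solve_input_rate
from reverb.types import BinnedActivity, BranchingParams, SpikeRaster


def geometric_slopes(b, m, k_max, dt=4.0):
    k = np.arange(1, k_max + 1)
    return RegressionSlopes(
        lags=k, slopes=b * m**k, n_pairs=np.full(k_max, 1000), dt=dt
    )


class TestBinSpikes:
    def test_halfopen_bins_and_trailing_drop(self):
        raster = SpikeRaster([0, 0, 0, 0], [0.001, 0.005, 0.006, 0.009])
        # t_stop defaults to the last spike (9 ms): only 2 whole 4-ms bins
        assert bin_spikes(raster, 4.0).counts.tolist() == [1, 2]

    def test_recording_length_keeps_last_bin(self):
        raster = SpikeRaster([0, 0, 0, 0], [0.001, 0.005, 0.006, 0.009], t_stop=0.012)
        assert bin_spikes(raster, 4.0).counts.tolist() == [1, 2, 1]

    def test_poisson_unit_rate(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.exponential(1 / 7.25, size=20_000))
        raster = SpikeRaster(np.zeros(t.size, int), t)
        act = bin_spikes(raster, 4.0)
        assert act.mean == pytest.approx(7.25 * 0.004, rel=0.05)

    def test_fifty_units_pooled_rate(self):
        rng = np.random.default_rng(1)
        units, times = [], []
        for u in range(50):
            t = np.cumsum(rng.exponential(1 / 7.25, size=800))
            times.append(t)
            units.append(np.full(t.size, u))
        raster = SpikeRaster(
            np.concatenate(units), np.concatenate(times), t_stop=100.0
        )
        act = bin_spikes(raster, 4.0)
        assert act.mean == pytest.approx(1.45, rel=0.05)

    def test_empty_raster_rejected(self):
        raster = SpikeRaster(np.empty(0, int), np.empty(0), t_stop=1.0)
        with pytest.raises(ValueError):
            bin_spikes(raster, 4.0)

    def test_negative_times_rejected_at_construction(self):
        with pytest.raises(ValueError):
            SpikeRaster([0], [-0.5])


class TestRegressionSlopes:
    def test_matches_independent_ols(self, rev_counts):
        slopes = regression_slopes(rev_counts, 20)
        a = rev_counts.counts.astype(float)
        for k in (1, 5, 20):
            ref = stats.linregress(a[:-k], a[k:]).slope
            assert abs(slopes.slopes[k - 1] - ref) < 1e-12

    def test_exact_halving_sequence(self):
        a = BinnedActivity(2 ** np.arange(12, 0, -1), dt=4.0)
        slopes = regression_slopes(a, 2)
        assert slopes.slopes[0] == pytest.approx(0.5, abs=1e-12)

    def test_iid_poisson_uncorrelated(self):
        rng = np.random.default_rng(2)
        act = BinnedActivity(rng.poisson(5.0, 200_000), dt=4.0)
        slopes = regression_slopes(act, 10)
        assert np.all(np.abs(slopes.slopes) < 0.02)

    def test_fully_sampled_branching(self, pop_m09):
        slopes = regression_slopes(pop_m09, 20)
        assert np.allclose(slopes.slopes, 0.9 ** slopes.lags, atol=0.02)

    def test_pair_counts(self, rev_counts):
        slopes = regression_slopes(rev_counts, 3)
        assert slopes.n_pairs.tolist() == [
            len(rev_counts) - 1,
            len(rev_counts) - 2,
            len(rev_counts) - 3,
        ]

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            regression_slopes(BinnedActivity(np.full(1000, 3), dt=4.0), 10)


class TestFitExponential:
    def test_noiseless_recovery_to_solver_tolerance(self):
        fit = fit_exponential(geometric_slopes(0.5, 0.98, 150))
        assert abs(fit.m_hat - 0.98) < 1e-10
        assert abs(fit.b_hat - 0.5) < 1e-10

    def test_tau_identity(self):
        fit = fit_exponential(geometric_slopes(0.3, 0.98, 150))
        assert fit.tau_hat == pytest.approx(-4.0 / np.log(fit.m_hat), abs=1e-12)
        assert fit.tau_hat == pytest.approx(198.0, abs=0.1)

    def test_subsampled_run_recovers_m(self, rev_counts):
        fit = mr_estimate(rev_counts, 150)
        assert fit.m_hat == pytest.approx(0.98, abs=0.005)

    def test_b_flag(self):
        fit = fit_exponential(geometric_slopes(1.5, 0.9, 50))
        assert fit.flags["b_above_one"]

    def test_too_few_lags(self):
        with pytest.raises(ValueError):
            regression_slopes(BinnedActivity(np.arange(100), dt=4.0), 1)


class TestConventionalEstimate:
    def test_unbiased_under_full_sampling(self, rev_run):
        conv = conventional_estimate(rev_run.full_counts)
        assert conv == pytest.approx(0.98, abs=0.005)

    def test_strong_downward_bias_under_subsampling(self, rev_counts):
        conv = conventional_estimate(rev_counts)
        assert conv < 0.5  # true m is 0.98

    def test_single_unit_near_zero(self, rev_run):
        from reverb.simulation import subsample

        sub = subsample(rev_run, 1, seed=3)
        assert conventional_estimate(sub) < 0.1

    def test_bias_ordering_conventional_below_mr(self, rev_counts):
        conv = conventional_estimate(rev_counts)
        mr = mr_estimate(rev_counts, 150).m_hat
        assert conv <= mr


class TestSubsamplingInvariance:
    def test_median_flat_and_b_monotone(self, rev_run):
        sizes = [10, 25, 50]
        curve = subsampling_invariance_curve(
            rev_run, sizes, repeats=10, k_max=150, seed=0
        )
        meds = curve["median_m"].to_numpy()
        assert np.all(np.abs(meds - 0.98) < 0.01)

    def test_b_decreases_with_subsampling(self, rev_run):
        from reverb.simulation import subsample

        b_vals = []
        for n_prime in (5, 25, 50):
            est = mr_estimate(subsample(rev_run, n_prime, seed=9), 150)
            b_vals.append(est.b_hat)
        assert b_vals[0] < b_vals[1] < b_vals[2]

    def test_full_population_b_near_one(self, rev_run):
        est = mr_estimate(rev_run.full_counts, 150)
        assert est.b_hat == pytest.approx(1.0, abs=0.05)

    def test_ai_no_detectable_correlation(self, ai_run):
        # at m=0 the decay base is unidentified (any m fits with b ~ 0); the
        # identifiable quantity is the fitted correlation amplitude b*m = r_1
        from reverb.simulation import subsample

        for n_prime, seed in ((10, 1), (50, 2)):
            est = mr_estimate(subsample(ai_run, n_prime, seed), 20)
            assert abs(est.b_hat * est.m_hat) < 0.01


class TestConfidenceInterval:
    def test_interval_covers_true_m(self, rev_counts):
        est = mr_estimate(rev_counts, 150)
        params = BranchingParams(
            m=0.98, h=5.8, N=10_000, n=50, L=len(rev_counts), seed=0
        )
        ci = confidence_interval(est, params, B=20, seed=4)
        lo, hi = ci["m_5_95"]
        assert lo < 0.98 < hi
        assert est.ci_m_16_84 is not None
        # tau interval consistent with the algebraic identity
        assert est.ci_tau_5_95[0] == pytest.approx(-4 / np.log(hi), abs=1e-9)

    def test_requires_two_replicates(self, rev_counts):
        est = mr_estimate(rev_counts, 150)
        with pytest.raises(ValueError):
            confidence_interval(est, BranchingParams(m=0.9, h=29, L=1000), B=1)


class TestWindowEstimates:
    def test_295s_yields_59_windows(self):
        params = BranchingParams(m=0.9, h=29.0, N=10_000, n=50, L=73_750, seed=21)
        counts = simulate_subsampled_counts(params)
        report = window_estimates(counts, 5.0, k_max=40, seed=1)
        assert report.window_m.size == 59

    def test_stationary_trace_passes_levene(self):
        params = BranchingParams(m=0.9, h=29.0, N=10_000, n=50, L=60_000, seed=30)
        counts = simulate_subsampled_counts(params)
        report = window_estimates(counts, 5.0, k_max=40, seed=2)
        assert report.variability_p > 0.05
        assert report.passed

    def test_too_short_trace_rejected(self):
        counts = BinnedActivity(np.random.default_rng(0).poisson(2, 1500), dt=4.0)
        with pytest.raises(ValueError):
            window_estimates(counts, 5.0)


class TestConsistencyBattery:
    def _counts(self, seed, h_t=None, L=60_000):
        params = BranchingParams(m=0.9, h=29.0, N=10_000, n=50, L=L, seed=seed)
        return simulate_subsampled_counts(params, h_t=h_t)

    def test_stationary_trace_passes(self):
        checks = consistency_tests(self._counts(40), k_max=40, seed=3)
        assert checks.passed

    def test_rate_ramp_fails_trend(self):
        L = 60_000
        h_t = 29.0 * np.linspace(1.0, 2.0, L)
        checks = consistency_tests(self._counts(41, h_t=h_t), k_max=40, seed=3)
        assert not checks.no_trend
        assert not checks.passed

    def test_step_change_flagged(self):
        L = 60_000
        h_t = np.full(L, 29.0)
        h_t[L // 2 :] *= 2
        checks = consistency_tests(self._counts(42, h_t=h_t), k_max=40, seed=3)
        assert not checks.passed

    def test_power_law_slopes_fail_adequacy(self):
        k = np.arange(1, 151)
        slopes = RegressionSlopes(
            lags=k, slopes=0.5 * k**-0.5, n_pairs=np.full(150, 1000), dt=4.0
        )
        bics = _fit_candidates(slopes)
        assert min(bics, key=bics.get) == "power_law"

    def test_exponential_slopes_pass_adequacy(self):
        bics = _fit_candidates(geometric_slopes(0.4, 0.95, 150))
        assert min(bics, key=bics.get) in ("exponential", "exponential_offset")
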