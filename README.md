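# reverb

Branching-network simulation and subsampling-invariant branching-ratio
estimation for spiking population activity.

The package implements a minimal model of cortical spike propagation — a
branching process with immigration, mapped onto a finite random network with
annealed disorder — together with the multistep-regression (MR) estimator of
the branching ratio `m`. The MR estimator fits the geometric decay of the
regression slopes `r_k = b·m^k` of binned population counts, which makes it
invariant to spatial subsampling (observing only `n` of `N` neurons): the
unknown subsampling factor `b` is partialled out, unlike the conventional
lag-1 regression estimator, which is strongly biased towards 0. On top of the
estimator the package provides the full validation suite (ISI/CV, Fano
factors, activity distributions, avalanche statistics with model-likelihood
comparison, pairwise spike-count correlations, autocorrelation functions) and
the prediction suite (single-extra-spike perturbation cascades,
susceptibility `1/(1−m)`, external-input fraction `1−m`, intrinsic timescale
`τ = −Δt/ln m`).

## Library overview

| module               | contents |
|----------------------|----------|
| `reverb.types`       | `SpikeRaster`, `BinnedActivity`, `BranchingParams`, `NetworkRun` |
| `reverb.simulation`  | population- and network-level simulators, matched-input solver `h = R·Δt·N·(1−m)`, subsampling |
| `reverb.estimation`  | regression slopes, exponential fit (MR), conventional estimator, bootstrap CIs, window estimates, consistency battery |
| `reverb.spikestats`  | ISI/CV, Fano curves, activity distributions, avalanches + likelihood, `r_sc`, autocorrelation |
| `reverb.predictions` | perturbation cascades (descendant-tree and paired protocols), closed-form state summary |
| `reverb.pipeline`    | matched-model construction (AI / reverberating / near-critical), validation report, one-call `full_report` |
| `reverb.io`          | plain-text raster/count IO, synthetic fixture generator |

```python
from reverb import BranchingParams, simulate_network, mr_estimate

params = BranchingParams(m=0.98, h=5.8, N=10_000, n=50, dt=4.0, L=10**6, seed=1)
run = simulate_network(params)
est = mr_estimate(run.sampled_counts, k_max=150)
print(est.m_hat, est.tau_hat)   # ~0.98, ~198 ms
```

## Command line

The console script `reverb` exposes the workflow:

```bash
# simulate a reverberating network and write raster + counts
reverb simulate --m 0.98 --rate 7.25 --n 50 --steps 100000 --seed 1 \
    --out-raster raster.tsv --out-counts counts.txt

# estimate m from the raster (with optional bootstrap CIs)
reverb estimate --raster raster.tsv --kmax 150 -B 100 --json-out report.json

# perturbation cascades and the closed-form state summary
reverb perturb --m 0.98 --trials 500 --out perturbations.tsv
reverb summary --m 0.98

# full pipeline: estimate, build matched models, validate, predict
reverb validate --raster raster.tsv --kmax 150 --out full_report.json

# deterministic synthetic recordings with ground truth
reverb fixtures --kind reverberating --seed 1 --out fixtures/
```

Rasters are 2-column tab-delimited text (`unit_id`, `spike_time_s`); count
traces are 1- or 2-column integer text; `#` starts a comment.

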