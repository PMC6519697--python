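"""Plain-text readers/writers and the seeded fixture generator.

Rasters are 2-column tab-delimited text (unit_id, spike_time in seconds, 6
decimals); count traces are 1-column integers or 2-column (bin_index, count).
Lines starting with '#' are comments; raster headers may carry metadata keys
(``# key = value``) such as the recording length.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .simulation import simulate_network, solve_input_rate
from .types import BinnedActivity, BranchingParams, NetworkRun, SpikeRaster

__all__ = [
    "read_raster",
    "write_raster",
    "read_counts",
    "write_counts",
    "make_fixture",
    "FIXTURE_KINDS",
]


def read_raster(path) -> SpikeRaster:
    """Parse a 2-column (unit_id, spike_time_s) delimited text file."""
    path = Path(path)
    units = []
    times = []
    t_stop = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    if key.strip() == "t_stop":
                        t_stop = float(val)
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                units.append(int(parts[0]))
                times.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable line {line!r}") from exc
    if not times:
        raise ValueError(f"{path}: no spikes found")
    return SpikeRaster(np.array(units), np.array(times), t_stop=t_stop)


def write_raster(raster: SpikeRaster, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# unit_id\tspike_time_s\n")
        fh.write(f"# t_stop = {raster.t_stop:.6f}\n")
        order = np.lexsort((raster.unit_ids, raster.times))
        for u, t in zip(raster.unit_ids[order], raster.times[order]):
            fh.write(f"{u}\t{t:.6f}\n")


def read_counts(path, dt: float = 4.0) -> BinnedActivity:
    """Read a count trace; accepts 1-column or 2-column (bin_index, count)."""
    data = np.loadtxt(path, comments="#", ndmin=2, dtype=np.int64)
    if data.shape[1] == 1:
        counts = data[:, 0]
    elif data.shape[1] == 2:
        order = np.argsort(data[:, 0])
        counts = data[order, 1]
    else:
        raise ValueError("count files must have 1 or 2 columns")
    return BinnedActivity(counts, dt=dt)


def write_counts(activity: BinnedActivity, path, with_index: bool = False) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# dt_ms = {activity.dt}\n")
        if with_index:
            for i, c in enumerate(activity.counts):
                fh.write(f"{i}\t{c}\n")
        else:
            for c in activity.counts:
                fh.write(f"{c}\n")


FIXTURE_KINDS = ("AI", "reverberating", "near_critical", "step_change", "ramp")

_FIXTURE_M = {"AI": 0.0, "reverberating": 0.98, "near_critical": 0.9999}


def make_fixture(
    kind: str,
    seed: int = 0,
    duration_s: float = 295.0,
    n: int = 50,
    rate: float = 7.25,
    N: int = 10_000,
    dt: float = 4.0,
) -> Tuple[SpikeRaster, dict]:
    """Deterministic synthetic recording with ground-truth metadata.

    Stationary kinds emulate the matched models (defaults: 295 s, 50 sampled
    units, 7.25 Hz).  ``step_change`` doubles the input rate halfway through;
    ``ramp`` ramps it linearly to double — both embed known non-stationarities
    for exercising the consistency tests.

    Returns the sampled raster and a JSON-serializable ground-truth dict.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    L = int(round(duration_s * 1000.0 / dt))
    m = _FIXTURE_M.get(kind, 0.98)
    h = solve_input_rate(rate, dt, N, m)
    params = BranchingParams(m=m, h=h, N=N, n=n, dt=dt, L=L, seed=seed)
    h_t = None
    if kind == "step_change":
        h_t = np.full(L, h)
        h_t[L // 2 :] *= 2.0
    elif kind == "ramp":
        h_t = h * np.linspace(1.0, 2.0, L)
    run = simulate_network(params, h_t=h_t)
    truth = {
        "kind": kind,
        "m": m,
        "h": h,
        "N": N,
        "n": n,
        "rate_hz": rate,
        "dt_ms": dt,
        "L": L,
        "duration_s": duration_s,
        "seed": seed,
        "nonstationary": kind in ("step_change", "ramp"),
    }
    return run.sampled_raster, truth


def write_fixture(kind: str, out_dir, seed: int = 0, **kwargs) -> dict:
    """Write a fixture raster plus its ground-truth JSON into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raster, truth = make_fixture(kind, seed=seed, **kwargs)
    write_raster(raster, out_dir / f"{kind}_raster.tsv")
    with (out_dir / f"{kind}_truth.json").open("w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
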