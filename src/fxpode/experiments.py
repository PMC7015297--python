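"""Reproduction drivers: spike-lag analysis, SR ensembles, sweeps, traces.

All comparisons are against the binary64 arithmetic reference running the
*same* unrolled solver, so every reported difference is arithmetic error.
Lag sign convention: ``lag(n) = t_test(n) - t_ref(n)``; positive means the
test spike arrives late (lag), negative means it leads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fixedpoint import FULL
from .neuron import InputSpec, NeuronParams, SimResult, SolverConfig, run

__all__ = [
    "EnsembleSummary",
    "LagSeries",
    "dither_sweep",
    "lag_series",
    "spike_lag",
    "sr_bits_sweep",
    "sr_ensemble",
    "summaries_to_frame",
    "trace_compare",
]


def spike_lag(test: SimResult, ref: SimResult, n: int) -> float:
    """Lag of the ``n``-th spike (1-based), in ms; NaN if the test run never
    produced that spike (the no-spike marker, e.g. underflow regimes)."""
    if n < 1:
        raise ValueError("spike index is 1-based")
    if ref.n_spikes < n:
        raise ValueError(f"reference run has only {ref.n_spikes} spikes")
    if test.n_spikes < n:
        return float("nan")
    return float(test.spike_times[n - 1] - ref.spike_times[n - 1])


@dataclass
class LagSeries:
    """Per-spike lag of one test run against the reference."""

    lags: np.ndarray  # NaN-padded to the reference spike count
    neuron: str
    solver: str
    backend: str
    n_spikes: int  # spikes present in the test run (non-NaN prefix)


def lag_series(test: SimResult, ref: SimResult, n_spikes: Optional[int] = None) -> LagSeries:
    n = int(n_spikes if n_spikes is not None else ref.n_spikes)
    if ref.n_spikes < n:
        raise ValueError("reference run has too few spikes")
    m = min(n, test.n_spikes)
    lags = np.full(n, np.nan)
    lags[:m] = test.spike_times[:m] - ref.spike_times[:n][:m]
    md = test.metadata
    backend = md.get("backend", "?")
    if md.get("rounding") and backend == "FIXED":
        backend = f"FIXED/{md['rounding']}"
    return LagSeries(lags=lags, neuron=md.get("neuron", ""), solver=md.get("solver", ""),
                     backend=backend, n_spikes=m)


@dataclass
class EnsembleSummary:
    """Per-spike mean and sample SD of lag over R runs."""

    mean: np.ndarray
    sd: np.ndarray  # sample SD, n-1 denominator
    seeds: tuple
    R: int
    n_spikes: int
    metadata: dict = field(default_factory=dict)

    def at(self, n: int) -> tuple[float, float]:
        """(mean, sd) of the lag of the ``n``-th spike, 1-based."""
        return float(self.mean[n - 1]), float(self.sd[n - 1])


def sr_ensemble(
    params: NeuronParams,
    input_spec: InputSpec,
    cfg: SolverConfig,
    ref: SimResult,
    R: int,
    base_seed: int = 0,
    *,
    spikes: Optional[int] = None,
    seeds: Optional[Sequence[int]] = None,
    **run_kwargs,
) -> EnsembleSummary:
    """Run the configuration R times with distinct seeds and summarize lags.

    Seeds default to ``base_seed .. base_seed + R - 1``; an explicit seed
    list must contain R distinct values.
    """
    if R < 2:
        raise ValueError("an ensemble needs R >= 2 runs")
    if seeds is None:
        seeds = tuple(base_seed + r for r in range(R))
    seeds = tuple(seeds)
    if len(seeds) != R or len(set(seeds)) != R:
        raise ValueError("seeds must be R distinct values")
    n = int(spikes if spikes is not None else ref.n_spikes)
    rows = np.full((R, n), np.nan)
    for j, s in enumerate(seeds):
        res = run(params, input_spec, cfg, spikes=n, seed=s, **run_kwargs)
        rows[j] = lag_series(res, ref, n).lags
    return EnsembleSummary(
        mean=np.nanmean(rows, axis=0),
        sd=np.where(np.isnan(rows).any(axis=0), np.nan, np.std(rows, axis=0, ddof=1)),
        seeds=seeds, R=R, n_spikes=n,
        metadata={**cfg.describe(), "neuron": params.label},
    )


def sr_bits_sweep(
    params: NeuronParams,
    input_spec: InputSpec,
    cfg: SolverConfig,
    ref: SimResult,
    k_list: Sequence = (2, 4, 6, 12, FULL),
    R: int = 10,
    base_seed: int = 0,
    *,
    spikes: Optional[int] = None,
    **run_kwargs,
) -> dict:
    """SR comparison-width sweep; seeds are reused across k values."""
    out = {}
    for k in k_list:
        cfg_k = replace(cfg, sr_bits=k)
        key = "FULL" if k is FULL else int(k)
        out[key] = sr_ensemble(params, input_spec, cfg_k, ref, R, base_seed,
                               spikes=spikes, **run_kwargs)
    return out


def dither_sweep(
    params: NeuronParams,
    input_spec: InputSpec,
    cfg: SolverConfig,
    ref: SimResult,
    sd_lsb_list: Sequence[float] = (0.0, 1.0, 10.0, 100.0, 1000.0, 10000.0),
    repeats: int = 10,
    base_seed: int = 0,
    *,
    spike_index: int = 650,
    **run_kwargs,
) -> dict:
    """Gaussian input-dither sweep: lag stats of one spike per noise level.

    Returns ``{sd_lsb: (mean lag, sd, n_valid)}`` over ``repeats`` seeds.
    A NaN mean marks levels where runs stopped spiking.
    """
    out = {}
    for level in sd_lsb_list:
        spec = replace(input_spec, dither_sd_lsb=float(level))
        lags = []
        for r in range(repeats):
            res = run(params, spec, cfg, spikes=spike_index, seed=base_seed + r, **run_kwargs)
            lags.append(spike_lag(res, ref, spike_index))
        lags = np.array(lags)
        valid = lags[~np.isnan(lags)]
        mean = float(np.mean(valid)) if valid.size else float("nan")
        sd = float(np.std(valid, ddof=1)) if valid.size > 1 else 0.0
        out[float(level)] = (mean, sd, int(valid.size))
    return out


def trace_compare(
    params: NeuronParams,
    input_spec: InputSpec,
    configs: dict[str, SolverConfig],
    window: tuple[float, float],
    *,
    base_seed: int = 0,
    R: int = 1,
    ensemble_labels: Sequence[str] = (),
    **run_kwargs,
) -> dict:
    """Aligned membrane-potential traces over a time window (ms).

    Labels listed in ``ensemble_labels`` are run R times with distinct seeds
    and reported as per-step mean and SD; others as a single trace.
    """
    t0, t1 = window
    out = {}
    for label, cfg in configs.items():
        h = float(cfg.h)
        i0, i1 = int(round(t0 / h)), int(round(t1 / h))
        reps = R if label in ensemble_labels else 1
        traces = []
        for r in range(reps):
            res = run(params, input_spec, cfg, duration=t1, seed=base_seed + r,
                      record=True, **run_kwargs)
            traces.append(res.v_trace[i0:i1])
        arr = np.vstack(traces)
        t = (np.arange(i0, i1) + 1) * h
        entry = {"t": t, "v": arr.mean(axis=0)}
        if reps > 1:
            entry["v_sd"] = arr.std(axis=0, ddof=1)
        out[label] = entry
    return out


def summaries_to_frame(summaries: dict, spike_index: Optional[int] = None) -> pd.DataFrame:
    """Tidy table of ensemble summaries keyed by sweep value."""
    rows = []
    for key, s in summaries.items():
        n = spike_index if spike_index is not None else s.n_spikes
        mean, sd = s.at(n)
        rows.append({"key": key, "spike": n, "mean_lag_ms": mean, "sd_ms": sd,
                     "R": s.R, **s.metadata})
    return pd.DataFrame(rows)
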