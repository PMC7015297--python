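"""Simulation driver: configuration, the step/run loop, and results.

Two engines execute the same arithmetic: a plain-Python object layer (the
reference implementation, used for short runs and parity tests) and the
compiled numba kernels in :mod:`fxpode.neuron.kernel` (used for the long
spike-timing experiments).  ``engine="auto"`` picks the kernel whenever the
configuration supports it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Union

import numpy as np

from ..fixedpoint import FULL, FixedValue, RoundingMode, RoundingSpec, as_fraction, encode
from ..prng import Algorithm, GeneratorState, seed_words
from . import kernel
from .backends import FixedBackend, FloatBackend
from .model import (
    CONST_NAMES,
    ConstantsMode,
    FixedConstants,
    FloatConstants,
    InputKind,
    InputSpec,
    NeuronParams,
    NeuronState,
    float32_value,
    make_constants,
)
from .solvers import Solver, step_algebra

__all__ = [
    "Backend",
    "FormatSet",
    "SimResult",
    "Solver",
    "SolverConfig",
    "esr_step",
    "reference_run",
    "run",
]


class Backend(str, enum.Enum):
    F64 = "F64"
    F32 = "F32"
    FIXED = "FIXED"


class FormatSet(str, enum.Enum):
    BITS32 = "BITS32"  # state s16.15, sub-unity constants u0.32
    BITS16 = "BITS16"  # state s8.7,   sub-unity constants u0.16


_SOLVER_IDS = {
    Solver.RK2_MIDPOINT: 0,
    Solver.RK2_TRAPEZOID: 1,
    Solver.RK3_HEUN: 2,
    Solver.CHAN_TSAI: 3,
}
_RMODE_IDS = {RoundingMode.RD: 0, RoundingMode.RN: 1, RoundingMode.SR: 2}
_ALG_IDS = {Algorithm.KISS99: 0, Algorithm.LFSR33: 1, Algorithm.RANQD1: 2}


@dataclass(frozen=True)
class SolverConfig:
    """Which solver, arithmetic backend, rounding and formats to run."""

    solver: Solver = Solver.RK2_MIDPOINT
    backend: Backend = Backend.F64
    rounding: RoundingMode = RoundingMode.RN
    sr_bits: Union[int, object] = FULL
    format_set: FormatSet = FormatSet.BITS32
    h: Fraction = Fraction(1, 10)
    constants_mode: ConstantsMode = ConstantsMode.EXACT_NEAREST
    rng_algorithm: Algorithm = Algorithm.KISS99

    def __post_init__(self):
        object.__setattr__(self, "solver", Solver(self.solver))
        object.__setattr__(self, "backend", Backend(self.backend))
        object.__setattr__(self, "rounding", RoundingMode(self.rounding))
        object.__setattr__(self, "format_set", FormatSet(self.format_set))
        object.__setattr__(self, "h", as_fraction(self.h))
        object.__setattr__(self, "constants_mode", ConstantsMode(self.constants_mode))
        object.__setattr__(self, "rng_algorithm", Algorithm(self.rng_algorithm))
        if self.h <= 0:
            raise ValueError("timestep must be positive")

    def describe(self) -> dict:
        return {
            "solver": self.solver.value,
            "backend": self.backend.value,
            "rounding": self.rounding.value if self.backend is Backend.FIXED else None,
            "sr_bits": None if self.sr_bits is FULL else self.sr_bits,
            "format_set": self.format_set.value,
            "h": float(self.h),
            "constants_mode": self.constants_mode.value,
            "rng_algorithm": self.rng_algorithm.value,
        }


@dataclass
class SimResult:
    """Spike times (ms), optional state traces, and run diagnostics."""

    spike_times: np.ndarray
    h: float
    n_steps: int
    saturation_count: int = 0
    v_trace: Optional[np.ndarray] = None
    u_trace: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


def initial_state(params: NeuronParams) -> tuple[Fraction, Fraction]:
    """Standard resting start: v0 = -65, u0 = b*v0."""
    v0 = Fraction(-65)
    return v0, params.b * v0


def _f32(x) -> float:
    return float(float32_value(as_fraction(x)))


def _needs_python_engine(cfg: SolverConfig) -> bool:
    return cfg.constants_mode is ConstantsMode.STOCHASTIC_SELECT


def run(
    params: NeuronParams,
    input_spec: InputSpec,
    cfg: SolverConfig,
    *,
    duration: Optional[float] = None,
    spikes: Optional[int] = None,
    seed: Optional[int] = None,
    record: bool = False,
    engine: str = "auto",
    max_duration: float = 400_000.0,
) -> SimResult:
    """Simulate until ``duration`` (ms) or until ``spikes`` spikes occurred.

    The generator seeded with ``seed`` drives stochastic rounding, input
    dither and stochastic constant selection; identical configuration and
    seed give identical results on either engine.
    """
    if duration is None and spikes is None:
        raise ValueError("give a duration and/or a spike target")
    h = float(cfg.h)
    n_steps = math.ceil((duration if duration is not None else max_duration) / h)
    if engine == "auto":
        engine = "python" if _needs_python_engine(cfg) else "numba"
    if engine == "numba" and _needs_python_engine(cfg):
        raise ValueError("stochastic constant selection runs on the python engine only")

    consts = make_constants(
        params, cfg.h, backend=cfg.backend.value,
        format_set=cfg.format_set.value, mode=cfg.constants_mode,
    )
    runner = _run_numba if engine == "numba" else _run_python
    result = runner(params, input_spec, cfg, consts, n_steps, spikes or 0, seed, record)
    result.metadata.update(
        neuron=params.label, seed=seed, engine=engine, input=input_spec.kind.value,
        dither_sd_lsb=input_spec.dither_sd_lsb, **cfg.describe(),
    )
    return result


def reference_run(
    params: NeuronParams,
    input_spec: InputSpec,
    solver: Solver,
    h="0.1",
    **kwargs,
) -> SimResult:
    """The arithmetic reference: the same ESR algebra in binary64."""
    cfg = SolverConfig(solver=Solver(solver), backend=Backend.F64, h=as_fraction(h))
    return run(params, input_spec, cfg, **kwargs)


# ---------------------------------------------------------------------------
# numba engine
# ---------------------------------------------------------------------------

def _input_plan(input_spec: InputSpec, cfg: SolverConfig):
    recompute = input_spec.dither_sd_lsb > 0 or input_spec.kind is InputKind.EXP_DECAY
    i_base = float(input_spec.magnitude)
    if cfg.backend is Backend.F32:
        i_base = _f32(input_spec.magnitude)
    decay = math.exp(-float(cfg.h) / input_spec.tau) if input_spec.kind is InputKind.EXP_DECAY else 1.0
    return recompute, i_base, decay


def _run_numba(params, input_spec, cfg, consts, n_steps, spike_target, seed, record):
    solver_id = _SOLVER_IDS[cfg.solver]
    alg = _ALG_IDS[cfg.rng_algorithm]
    st = np.array(seed_words(cfg.rng_algorithm, seed), dtype=np.int64)
    h = float(cfg.h)
    cap = spike_target if spike_target else n_steps
    spikes_buf = np.empty(cap, dtype=np.float64)
    v_trace = np.empty(n_steps if record else 0, dtype=np.float64)
    u_trace = np.empty(n_steps if record else 0, dtype=np.float64)
    recompute, i_base, decay = _input_plan(input_spec, cfg)
    dither_sd = input_spec.dither_sd_abs
    v0f, u0f = initial_state(params)

    if cfg.backend is Backend.FIXED:
        C = np.array([consts.values[k].raw for k in CONST_NAMES], dtype=np.int64)
        fmt = consts.state_fmt
        scale = float(1 << fmt.p)
        i_raw0 = encode(input_spec.magnitude, fmt, RoundingMode.RN).raw
        sat = np.zeros(1, dtype=np.int64)
        ns, steps = kernel.run_fixed(
            solver_id, C, fmt.p, consts.const_fmt.p,
            np.int64(fmt.raw_min), np.int64(fmt.raw_max),
            np.int64(consts.thr.raw), np.int64(consts.c.raw), np.int64(consts.d.raw),
            np.int64(encode(v0f, fmt, RoundingMode.RN).raw),
            np.int64(encode(u0f, fmt, RoundingMode.RN).raw),
            np.int64(i_raw0), recompute, 1 if input_spec.kind is InputKind.EXP_DECAY else 0,
            i_base, decay, dither_sd, scale,
            _RMODE_IDS[cfg.rounding], 0 if cfg.sr_bits is FULL else int(cfg.sr_bits),
            alg, st, h, n_steps, spike_target,
            spikes_buf, record, v_trace, u_trace, sat,
        )
        sat_count = int(sat[0])
    else:
        single = cfg.backend is Backend.F32
        C = np.array([consts.values[k] for k in CONST_NAMES], dtype=np.float64)
        i_val = _f32(input_spec.magnitude) if single else float(input_spec.magnitude)
        ns, steps = kernel.run_float(
            solver_id, C, single, consts.thr, consts.c, consts.d,
            float(v0f), float(u0f),
            i_val, recompute, 1 if input_spec.kind is InputKind.EXP_DECAY else 0,
            i_base, decay, dither_sd,
            alg, st, h, n_steps, spike_target,
            spikes_buf, record, v_trace, u_trace,
        )
        sat_count = 0
    return SimResult(
        spike_times=spikes_buf[: min(ns, cap)].copy(),
        h=h, n_steps=steps, saturation_count=sat_count,
        v_trace=v_trace[:steps] if record else None,
        u_trace=u_trace[:steps] if record else None,
    )


# ---------------------------------------------------------------------------
# python engine (reference implementation)
# ---------------------------------------------------------------------------

def _select_constants(consts: FixedConstants, g: GeneratorState) -> dict:
    """Stochastic constant selection: one 32-bit draw per constant, in order."""
    out = {}
    for name in CONST_NAMES:
        lo, hi, thresh = consts.select[name]
        if lo.raw == hi.raw:
            out[name] = lo
        else:
            out[name] = hi if g.next_u32() < thresh else lo
    return out


def _run_python(params, input_spec, cfg, consts, n_steps, spike_target, seed, record):
    g = GeneratorState(cfg.rng_algorithm, seed)
    h = float(cfg.h)
    recompute, i_base, decay = _input_plan(input_spec, cfg)
    dither_sd = input_spec.dither_sd_abs
    v0f, u0f = initial_state(params)
    fixed = cfg.backend is Backend.FIXED

    if fixed:
        fmt = consts.state_fmt
        scale = float(1 << fmt.p)
        rs = RoundingSpec(cfg.rounding, k=cfg.sr_bits,
                          rng=g if cfg.rounding is RoundingMode.SR else None)
        be = FixedBackend(fmt, consts.const_fmt, rs)
        v = encode(v0f, fmt, RoundingMode.RN)
        u = encode(u0f, fmt, RoundingMode.RN)
        thr, c_reset, d_add = consts.thr, consts.c, consts.d
        i_fixed = encode(input_spec.magnitude, fmt, RoundingMode.RN)
    else:
        be = FloatBackend(single=cfg.backend is Backend.F32)
        v, u = float(v0f), float(u0f)
        thr, c_reset, d_add = consts.thr, consts.c, consts.d
        i_fixed = _f32(input_spec.magnitude) if be.single else float(input_spec.magnitude)

    spike_times = []
    v_trace = np.empty(n_steps) if record else None
    u_trace = np.empty(n_steps) if record else None
    i_cur = i_base
    steps = 0
    for n in range(n_steps):
        C = _select_constants(consts, g) if getattr(consts, "select", None) else consts.values
        if recompute:
            x = i_cur
            if dither_sd > 0.0:
                x = x + dither_sd * g.gaussian()
            if fixed:
                raw = math.floor(x * scale + 0.5)
                raw = min(max(raw, fmt.raw_min), fmt.raw_max)
                iw = FixedValue(raw, fmt)
            else:
                iw = be._fl(x)
            if input_spec.kind is InputKind.EXP_DECAY:
                i_cur = i_cur * decay
        else:
            iw = i_fixed
        v1, u1 = step_algebra(cfg.solver, be, C, v, u, iw)
        if be.ge(v1, thr):
            spike_times.append((n + 1) * h)
            v1 = c_reset
            u1 = be.add(u1, d_add)
        v, u = v1, u1
        if record:
            v_trace[n] = float(v)
            u_trace[n] = float(u)
        steps = n + 1
        if spike_target and len(spike_times) >= spike_target:
            break
    return SimResult(
        spike_times=np.array(spike_times, dtype=np.float64),
        h=h, n_steps=steps, saturation_count=be.sat_count,
        v_trace=v_trace[:steps] if record else None,
        u_trace=u_trace[:steps] if record else None,
    )


def esr_step(state: NeuronState, I, params: NeuronParams, cfg: SolverConfig,
             g: Optional[GeneratorState] = None) -> tuple[NeuronState, bool]:
    """One solver step from ``state`` in the configured arithmetic.

    Convenience wrapper around the python engine: encodes the state into the
    backend's representation, performs one unrolled step, applies the
    threshold/reset rule, and decodes back to floats.
    """
    consts = make_constants(params, cfg.h, backend=cfg.backend.value,
                            format_set=cfg.format_set.value, mode=cfg.constants_mode)
    if cfg.backend is Backend.FIXED:
        fmt = consts.state_fmt
        rs = RoundingSpec(cfg.rounding, k=cfg.sr_bits,
                          rng=g if cfg.rounding is RoundingMode.SR else None)
        be = FixedBackend(fmt, consts.const_fmt, rs)
        v = encode(as_fraction(state.v), fmt, RoundingMode.RN)
        u = encode(as_fraction(state.u), fmt, RoundingMode.RN)
        iw = encode(as_fraction(I), fmt, RoundingMode.RN)
    else:
        be = FloatBackend(single=cfg.backend is Backend.F32)
        v, u, iw = float(state.v), float(state.u), be._fl(float(I))
    C = _select_constants(consts, g) if getattr(consts, "select", None) else consts.values
    v1, u1 = step_algebra(cfg.solver, be, C, v, u, iw)
    spike = be.ge(v1, consts.thr)
    if spike:
        v1 = consts.c
        u1 = be.add(u1, consts.d)
    return NeuronState(v=float(v1), u=float(u1)), spike
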