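"""Izhikevich model definition, parameter presets and constant encoding.

The model is the two-variable hybrid system

    dv/dt = 0.04*v**2 + 5*v + 140 - u + I
    du/dt = a*(b*v - u)

with a spike-and-reset rule: when v reaches 30 mV, v <- c and u <- u + d.

Constants are defined here as exact decimals and encoded into each
arithmetic backend's working representation.  For fixed-point backends every
constant smaller than one lives in the unsigned pure-fraction format
(u0.32, or u0.16 for the 16-bit set) and the remainder in the wide signed
state format, both round-to-nearest encoded; this is what makes e.g. 0.04
become exactly 0.040008544921875 in s16.15.
"""

from __future__ import annotations

import enum
import struct
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Union

from ..fixedpoint import (
    FixedFormat,
    FixedValue,
    RoundingMode,
    as_fraction,
    encode,
)

__all__ = [
    "CH",
    "FS",
    "RS",
    "PRESETS",
    "ConstantsMode",
    "FixedConstants",
    "FloatConstants",
    "InputSpec",
    "NeuronParams",
    "NeuronState",
    "izh_rhs",
    "izh_rhs_exact",
    "make_constants",
    "solver_coefficients",
]


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich parameter set ``(a, b, c, d)`` with a preset label."""

    a: Fraction
    b: Fraction
    c: Fraction
    d: Fraction
    label: str = ""

    @classmethod
    def make(cls, a, b, c, d, label="") -> "NeuronParams":
        return cls(as_fraction(a), as_fraction(b), as_fraction(c), as_fraction(d), label)


#: Regular spiking.
RS = NeuronParams.make("0.02", "0.2", -65, 8, "RS")
#: Fast spiking.
FS = NeuronParams.make("0.1", "0.2", -65, 2, "FS")
#: Chattering.
CH = NeuronParams.make("0.02", "0.2", -50, 2, "CH")

PRESETS = {"RS": RS, "FS": FS, "CH": CH}


@dataclass
class NeuronState:
    v: float
    u: float


class InputKind(str, enum.Enum):
    DC = "DC"
    EXP_DECAY = "EXP_DECAY"


@dataclass(frozen=True)
class InputSpec:
    """Input current: DC or a single exponentially decaying pulse.

    ``dither_sd_lsb`` scales per-step Gaussian input noise in multiples of
    the s16.15 LSB (2**-15), the convention used for the dither sweeps.
    """

    kind: InputKind = InputKind.DC
    magnitude: Fraction = Fraction("4.775")
    tau: float = 5.0
    dither_sd_lsb: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "kind", InputKind(self.kind))
        object.__setattr__(self, "magnitude", as_fraction(self.magnitude))
        if self.dither_sd_lsb < 0:
            raise ValueError("dither SD must be >= 0")

    @property
    def dither_sd_abs(self) -> float:
        return self.dither_sd_lsb * 2.0 ** -15


# Model constants, exact decimals.
_ALPHA = Fraction("0.04")
_BETA = Fraction("0.08")  # d(0.04 v^2)/dv factor used by the two-derivative solver
_FIVE = Fraction(5)
_C140 = Fraction(140)
_VTHRESH = Fraction(30)


def izh_rhs(state, I, params: NeuronParams):
    """Derivatives ``(dv, du)`` of the Izhikevich equations.

    Works on floats (float output) or exact rationals (Fraction output);
    the exact path is the oracle used to validate backend steps.
    """
    v, u = (state.v, state.u) if isinstance(state, NeuronState) else state
    if isinstance(v, (Fraction, int)) and isinstance(u, (Fraction, int)):
        v, u, I = as_fraction(v), as_fraction(u), as_fraction(I)
        dv = _ALPHA * v * v + _FIVE * v + _C140 - u + I
        du = params.a * (params.b * v - u)
        return dv, du
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + I
    du = float(params.a) * (float(params.b) * v - u)
    return dv, du


def izh_rhs_exact(v, u, I, params: NeuronParams) -> tuple[Fraction, Fraction]:
    """Exact-rational right-hand side (explicit oracle entry point)."""
    return izh_rhs((as_fraction(v), as_fraction(u)), as_fraction(I), params)


def solver_coefficients(h: Fraction) -> dict[str, Fraction]:
    """Timestep-derived coefficients of the unrolled solvers, exact."""
    h = as_fraction(h)
    return {
        "h": h,
        "h2": h / 2,
        "h3": h / 3,
        "h23": 2 * h / 3,
        "h4": h / 4,
        "h34": 3 * h / 4,
        "hh8": h * h / 8,
        "hh6": h * h / 6,
        "hh3": h * h / 3,
    }


class ConstantsMode(str, enum.Enum):
    #: Encode each exact decimal constant with round-to-nearest.
    EXACT_NEAREST = "EXACT_NEAREST"
    #: Round each constant to binary32 first (dither-protocol constants).
    F32_ROUNDED = "F32_ROUNDED"
    #: Hold both adjacent representable values; pick one per step stochastically.
    STOCHASTIC_SELECT = "STOCHASTIC_SELECT"


def float32_value(x: Fraction) -> Fraction:
    """Exact value of ``x`` rounded to the nearest binary32."""
    return Fraction(struct.unpack("f", struct.pack("f", float(x)))[0])


#: Constant names in the fixed order used everywhere (stochastic selection
#: consumes one draw per name in this order).
CONST_NAMES = (
    "alpha", "beta", "a", "b",            # sub-unity, held in the u-fract format
    "five", "c140",                        # state-format constants
    "h", "h2", "h3", "h23", "h4", "h34", "hh8", "hh6", "hh3",
)

_STATE_FORMAT_CONSTS = {"five", "c140"}


def _exact_constants(params: NeuronParams, h: Fraction) -> dict[str, Fraction]:
    vals = {"alpha": _ALPHA, "beta": _BETA, "a": params.a, "b": params.b,
            "five": _FIVE, "c140": _C140}
    vals.update(solver_coefficients(h))
    return vals


@dataclass
class FixedConstants:
    """Constant set encoded for a fixed-point backend."""

    state_fmt: FixedFormat
    const_fmt: FixedFormat
    values: dict[str, FixedValue]
    thr: FixedValue
    c: FixedValue
    d: FixedValue
    #: present only for stochastic constant selection
    select: Optional[dict[str, tuple[FixedValue, FixedValue, int]]] = None

    def fmt_of(self, name: str) -> FixedFormat:
        return self.state_fmt if name in _STATE_FORMAT_CONSTS else self.const_fmt


@dataclass
class FloatConstants:
    """Constant set for a floating-point backend (values are exact floats)."""

    single: bool
    values: dict[str, float]
    thr: float
    c: float
    d: float


def make_constants(
    params: NeuronParams,
    h,
    *,
    backend: str,
    format_set: str = "BITS32",
    mode: Union[ConstantsMode, str] = ConstantsMode.EXACT_NEAREST,
):
    """Build the backend-typed constant set for one solver configuration.

    For the FIXED backend, sub-unity constants are round-to-nearest encoded
    into the unsigned fraction format and the rest into the signed state
    format.  ``F32_ROUNDED`` first snaps each decimal to its nearest binary32
    value (and is a no-op for the F32 backend itself).
    ``STOCHASTIC_SELECT`` additionally stores, per constant, the two
    bracketing representable values and the 32-bit integer round-up
    threshold derived from the exact value.
    """
    mode = ConstantsMode(mode)
    h = as_fraction(h)
    exact = _exact_constants(params, h)
    if mode is ConstantsMode.F32_ROUNDED:
        exact = {k: float32_value(v) for k, v in exact.items()}

    if backend in ("F64", "F32"):
        single = backend == "F32"
        conv = (lambda x: float(float32_value(x))) if single else float
        return FloatConstants(
            single=single,
            values={k: conv(v) for k, v in exact.items()},
            thr=conv(_VTHRESH),
            c=conv(params.c),
            d=conv(params.d),
        )

    if backend != "FIXED":
        raise ValueError(f"unknown backend {backend!r}")
    if format_set == "BITS32":
        state_fmt, const_fmt = FixedFormat.parse("s16.15"), FixedFormat.parse("u0.32")
    elif format_set == "BITS16":
        state_fmt, const_fmt = FixedFormat.parse("s8.7"), FixedFormat.parse("u0.16")
    else:
        raise ValueError(f"unknown format set {format_set!r}")

    def enc(name: str, x: Fraction) -> FixedValue:
        fmt = state_fmt if name in _STATE_FORMAT_CONSTS else const_fmt
        return encode(x, fmt, RoundingMode.RN)

    values = {k: enc(k, v) for k, v in exact.items()}
    select = None
    if mode is ConstantsMode.STOCHASTIC_SELECT:
        select = {}
        for k, x in exact.items():
            fmt = state_fmt if k in _STATE_FORMAT_CONSTS else const_fmt
            lo = encode(x, fmt, RoundingMode.RD)
            resid = (x - lo.value) / fmt.epsilon  # in [0, 1)
            hi = FixedValue(lo.raw + 1, fmt) if resid else lo
            # round-up threshold against a 32-bit uniform draw
            thresh = (resid.numerator << 32) // resid.denominator
            select[k] = (lo, hi, thresh)
    return FixedConstants(
        state_fmt=state_fmt,
        const_fmt=const_fmt,
        values=values,
        thr=encode(_VTHRESH, state_fmt, RoundingMode.RN),
        c=encode(params.c, state_fmt, RoundingMode.RN),
        d=encode(params.d, state_fmt, RoundingMode.RN),
        select=select,
    )
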