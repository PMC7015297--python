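"""Generalized ``<sign, i, p>`` fixed-point formats and rounding primitives.

A fixed-point format has an optional sign bit, ``i`` integer bits and ``p``
fraction bits; every representable value is an integer multiple of the
machine epsilon ``2**-p``.  All arithmetic in this package is carried out on
exact integer *raw* values; rationals (`fractions.Fraction`) appear only at
the encode/decode boundary, which keeps every operation bit-exact and
testable against closed-form oracles.

Three rounding modes are provided:

``RD``
    round-down: 2's-complement truncation, i.e. floor toward minus infinity
    (not round-toward-zero).
``RN``
    round-to-nearest with ties rounded *up* (decided by the most significant
    discarded bit).
``SR``
    stochastic rounding: round up with probability equal to the discarded
    residual fraction, optionally comparing only the top ``k`` bits of the
    residual against a ``k``-bit uniform random integer.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Union

__all__ = [
    "FULL",
    "FixedFormat",
    "FixedValue",
    "RangeError",
    "RoundingMode",
    "RoundingSpec",
    "ACCUM",
    "LONG_FRACT",
    "ULONG_FRACT",
    "SHORT_ACCUM",
    "UFRACT",
    "FRACT",
    "as_fraction",
    "decode",
    "encode",
    "epsilon",
    "round_raw",
    "sr_add_truncate",
    "sr_kbit",
    "value_range",
]

Rational = Union[int, Fraction]


class RangeError(ValueError):
    """Raised when a value cannot be represented in the target format.

    Encoding never saturates silently: clamping is an explicit behaviour of
    the multiply/add stage, so an out-of-range constant definition is a
    configuration bug and surfaces as this error.
    """


class _Full(enum.Enum):
    FULL = "FULL"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "FULL"


#: Sentinel: stochastic rounding uses every available residual bit (capped at
#: the 32 bits of one generator draw).
FULL = _Full.FULL


class RoundingMode(str, enum.Enum):
    RD = "RD"
    RN = "RN"
    SR = "SR"


_FMT_RE = re.compile(r"^(?P<s>[su])(?P<i>\d+)\.(?P<p>\d+)$")


@dataclass(frozen=True)
class FixedFormat:
    """A ``<sign, i, p>`` fixed-point format descriptor.

    Parameters
    ----------
    signed
        Whether the format carries a sign bit (2's-complement).
    i
        Number of integer bits (>= 0).
    p
        Number of fraction bits (>= 0).
    """

    signed: bool
    i: int
    p: int

    def __post_init__(self) -> None:
        if self.i < 0 or self.p < 0:
            raise ValueError("integer and fraction bit counts must be >= 0")
        if self.w < 1:
            raise ValueError("word length must be >= 1")

    # -- derived quantities -------------------------------------------------

    @property
    def w(self) -> int:
        """Word length: ``i + p`` plus one sign bit if signed."""
        return self.i + self.p + (1 if self.signed else 0)

    @property
    def epsilon(self) -> Fraction:
        """Gap between neighbouring representable values, ``2**-p``."""
        return Fraction(1, 1 << self.p)

    @property
    def raw_min(self) -> int:
        return -(1 << (self.i + self.p)) if self.signed else 0

    @property
    def raw_max(self) -> int:
        return (1 << (self.i + self.p)) - 1

    @property
    def min_value(self) -> Fraction:
        return Fraction(self.raw_min, 1 << self.p)

    @property
    def max_value(self) -> Fraction:
        return Fraction(self.raw_max, 1 << self.p)

    # -- construction / display --------------------------------------------

    @classmethod
    def parse(cls, name: str) -> "FixedFormat":
        """Parse a format name such as ``"s16.15"`` or ``"u0.32"``."""
        m = _FMT_RE.match(name.strip())
        if m is None:
            raise ValueError(f"not a fixed-point format name: {name!r}")
        return cls(signed=m.group("s") == "s", i=int(m.group("i")), p=int(m.group("p")))

    def __str__(self) -> str:
        return f"{'s' if self.signed else 'u'}{self.i}.{self.p}"


def _coerce_format(fmt: Union[FixedFormat, str]) -> FixedFormat:
    return FixedFormat.parse(fmt) if isinstance(fmt, str) else fmt


#: ISO 18037 ``accum``: <s,16,15>.
ACCUM = FixedFormat(True, 16, 15)
#: ISO 18037 ``signed long fract``: <s,0,31>.
LONG_FRACT = FixedFormat(True, 0, 31)
#: ISO 18037 ``unsigned long fract``: <u,0,32>.
ULONG_FRACT = FixedFormat(False, 0, 32)
#: ISO 18037 ``short accum``: <s,8,7>.
SHORT_ACCUM = FixedFormat(True, 8, 7)
#: ISO 18037 ``unsigned fract``: <u,0,16>.
UFRACT = FixedFormat(False, 0, 16)
#: ISO 18037 ``signed fract``: <s,0,15>.
FRACT = FixedFormat(True, 0, 15)


@dataclass(frozen=True)
class FixedValue:
    """An exact raw integer paired with its format.

    ``saturated`` records whether a clamping event produced this value; it is
    metadata only and does not participate in equality.
    """

    raw: int
    fmt: FixedFormat
    saturated: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.fmt.raw_min <= self.raw <= self.fmt.raw_max):
            raise RangeError(
                f"raw value {self.raw} outside {self.fmt} raw range "
                f"[{self.fmt.raw_min}, {self.fmt.raw_max}]"
            )

    @property
    def value(self) -> Fraction:
        """Exact decoded value, ``raw * 2**-p``."""
        return Fraction(self.raw, 1 << self.fmt.p)

    def __float__(self) -> float:
        return float(self.value)

    def __repr__(self) -> str:
        sat = ", saturated" if self.saturated else ""
        return f"FixedValue({float(self.value)!r} @ {self.fmt}{sat})"


@dataclass
class RoundingSpec:
    """Rounding mode plus the stochastic-rounding configuration.

    ``k`` is the comparison bit width for SR: :data:`FULL` (default) uses
    every available residual bit, a positive integer uses only the top ``k``
    bits of both the residual and the random draw.  ``rng`` must expose
    ``next_u32()`` and is required iff ``mode`` is SR.
    """

    mode: RoundingMode
    k: Union[int, _Full] = FULL
    rng: object = None

    def __post_init__(self) -> None:
        self.mode = RoundingMode(self.mode)
        if self.k is not FULL and (not isinstance(self.k, int) or self.k < 1):
            raise ValueError("k must be FULL or a positive integer")
        if self.mode is RoundingMode.SR and self.rng is None:
            raise ValueError("SR rounding requires a generator handle")


RD = RoundingSpec(RoundingMode.RD)
RN = RoundingSpec(RoundingMode.RN)


def _coerce_spec(rs: Union[RoundingSpec, RoundingMode, str]) -> RoundingSpec:
    if isinstance(rs, RoundingSpec):
        return rs
    return RoundingSpec(RoundingMode(rs))


# ---------------------------------------------------------------------------
# Rational helpers
# ---------------------------------------------------------------------------

def as_fraction(x: Union[Rational, float, str]) -> Fraction:
    """Convert ``x`` to an exact :class:`~fractions.Fraction`.

    Strings are parsed as exact decimals (use these for constants like
    ``"0.04"``); floats convert to their exact binary64 value.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, str):
        return Fraction(x)
    return Fraction(x)


def epsilon(fmt: Union[FixedFormat, str]) -> Fraction:
    """Machine epsilon ``2**-p`` of ``fmt``, exact."""
    return _coerce_format(fmt).epsilon


def value_range(fmt: Union[FixedFormat, str]) -> tuple[Fraction, Fraction]:
    """Exact (min, max) representable values of ``fmt``."""
    fmt = _coerce_format(fmt)
    return fmt.min_value, fmt.max_value


# ---------------------------------------------------------------------------
# Integer rounding primitives
# ---------------------------------------------------------------------------

def round_raw(extended: int, f: int, rs: Union[RoundingSpec, RoundingMode, str]) -> int:
    """Drop the bottom ``f`` fraction bits of ``extended`` under ``rs``.

    This is the shared primitive behind :func:`encode` and the multiply
    stage.  RD is an arithmetic right shift (floor toward minus infinity for
    negatives, by 2's-complement truncation).  RN adds half an output LSB
    before the shift, which implements tie-up via the MSB of the discarded
    field.  SR rounds up with probability ``residual / 2**f``; a zero
    residual short-circuits without consuming a random draw, so exact
    operations stay deterministic.
    """
    if f < 0:
        raise ValueError("f must be >= 0")
    if f == 0:
        return extended
    rs = _coerce_spec(rs)
    if rs.mode is RoundingMode.RD:
        return extended >> f
    if rs.mode is RoundingMode.RN:
        return (extended + (1 << (f - 1))) >> f
    # SR
    resid = extended & ((1 << f) - 1)
    base = extended >> f
    if resid == 0:
        return base
    k = f if rs.k is FULL else min(rs.k, f)
    k = min(k, 32)  # one 32-bit generator draw per rounding event
    rand_k = rs.rng.next_u32() >> (32 - k)
    return sr_kbit(extended, f, k, rand_k)


def sr_kbit(extended: int, f: int, k: int, rand_k: int) -> int:
    """Stochastic rounding decided by the top ``k`` residual bits.

    Rounds up iff ``rand_k`` (a ``k``-bit uniform integer) is strictly less
    than the top ``k`` bits of the ``f``-bit residual.  With ``k == f`` this
    is exactly the full comparator form of stochastic rounding.
    """
    if not (1 <= k <= f):
        raise ValueError("need 1 <= k <= f")
    base = extended >> f
    resid = extended & ((1 << f) - 1)
    top = resid >> (f - k)
    return base + (1 if rand_k < top else 0)


def sr_add_truncate(extended: int, f: int, rand_f: int) -> int:
    """Adder-style stochastic rounding: add the random number, then truncate.

    ``(extended + rand_f) >> f`` produces a carry into the result bits iff
    ``rand_f >= 2**f - residual``.  This is the same Bernoulli event as the
    comparator form under the bit-complement of the draw: for every input,
    ``sr_add_truncate(x, f, r) == sr_kbit(x, f, f, 2**f - 1 - r)`` (verified
    exhaustively in the test suite).
    """
    if f < 0:
        raise ValueError("f must be >= 0")
    if not (0 <= rand_f < (1 << max(f, 1))):
        raise ValueError("rand_f must be an f-bit unsigned integer")
    return (extended + rand_f) >> f


# ---------------------------------------------------------------------------
# Encode / decode
# ---------------------------------------------------------------------------

def encode(
    x: Union[Rational, float, str],
    fmt: Union[FixedFormat, str],
    rs: Union[RoundingSpec, RoundingMode, str],
) -> FixedValue:
    """Round the exact rational ``x`` into ``fmt`` under ``rs``.

    RD floors to the next multiple of epsilon toward minus infinity, RN picks
    the nearest multiple with ties up, SR returns ``floor(x) + eps`` with
    probability ``(x - floor(x)) / eps``.  A result outside the representable
    range raises :class:`RangeError` (saturation is deliberately *not* the
    encoder's job).
    """
    fmt = _coerce_format(fmt)
    rs = _coerce_spec(rs)
    scaled = as_fraction(x) * (1 << fmt.p)
    floor_raw = scaled.numerator // scaled.denominator
    resid = scaled - floor_raw  # in [0, 1), units of one output LSB
    if rs.mode is RoundingMode.RD or resid == 0:
        raw = floor_raw
    elif rs.mode is RoundingMode.RN:
        raw = floor_raw + (1 if resid >= Fraction(1, 2) else 0)
    else:  # SR
        if rs.rng is None:
            raise ValueError("SR rounding requires a generator handle")
        k = 32 if rs.k is FULL else min(rs.k, 32)
        rand_k = rs.rng.next_u32() >> (32 - k)
        top = (resid.numerator << k) // resid.denominator  # floor(resid * 2**k)
        raw = floor_raw + (1 if rand_k < top else 0)
    if not (fmt.raw_min <= raw <= fmt.raw_max):
        raise RangeError(f"{x!r} rounds outside the range of {fmt}")
    return FixedValue(raw, fmt)


def decode(v: FixedValue) -> Fraction:
    """Exact value of ``v``: ``raw * 2**-p``."""
    return v.value
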