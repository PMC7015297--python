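"""Mixed-format fixed-point multiplication with rounding and saturation.

The multiply keeps the full-precision intermediate product (``p_a + p_b``
fraction bits, word length ``w_a + w_b - 1``), rounds it down to the output
format with the selected mode, then clamps to the output range.  Saturation
is silent but flagged on the result so simulations can count overflow
events.  Addition and subtraction of same-format values are exact apart from
saturation.

The ten named cases from the 32-bit and 16-bit format families are
registered configurations of the one generic engine.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional, Union

from .fixedpoint import (
    FULL,
    FixedFormat,
    FixedValue,
    RoundingMode,
    RoundingSpec,
    _coerce_format,
    _coerce_spec,
    round_raw,
)

__all__ = ["MulCase", "MUL_CASES", "add", "sub", "mul", "mul_reference"]


class MulCase:
    """An (input format a, input format b, output format) multiply setup."""

    def __init__(self, fmt_a, fmt_b, fmt_out) -> None:
        self.fmt_a = _coerce_format(fmt_a)
        self.fmt_b = _coerce_format(fmt_b)
        self.fmt_out = _coerce_format(fmt_out)
        if self.fmt_out.p > self.fmt_a.p + self.fmt_b.p:
            raise ValueError("output cannot carry more fraction bits than the product")

    @property
    def shift(self) -> int:
        """Fraction bits discarded when aligning the product to the output."""
        return self.fmt_a.p + self.fmt_b.p - self.fmt_out.p

    @property
    def name(self) -> str:
        return f"{self.fmt_a}x{self.fmt_b}"

    def __repr__(self) -> str:
        return f"MulCase({self.fmt_a} x {self.fmt_b} -> {self.fmt_out})"


#: The five 32-bit multiply cases and their 16-bit equivalents; the first
#: three of each family saturate into the wide signed type, the last two
#: into the signed fract type.
MUL_CASES: dict[str, MulCase] = {
    c.name: c
    for c in [
        MulCase("s16.15", "s16.15", "s16.15"),
        MulCase("s16.15", "s0.31", "s16.15"),
        MulCase("s16.15", "u0.32", "s16.15"),
        MulCase("u0.32", "u0.32", "s0.31"),
        MulCase("u0.32", "s0.31", "s0.31"),
        MulCase("s8.7", "s8.7", "s8.7"),
        MulCase("s8.7", "s0.15", "s8.7"),
        MulCase("s8.7", "u0.16", "s8.7"),
        MulCase("u0.16", "u0.16", "s0.15"),
        MulCase("u0.16", "s0.15", "s0.15"),
    ]
}


def _saturate(raw: int, fmt: FixedFormat) -> FixedValue:
    if raw < fmt.raw_min:
        return FixedValue(fmt.raw_min, fmt, saturated=True)
    if raw > fmt.raw_max:
        return FixedValue(fmt.raw_max, fmt, saturated=True)
    return FixedValue(raw, fmt)


def mul(
    a: FixedValue,
    b: FixedValue,
    fmt_out: Union[FixedFormat, str],
    rs: Union[RoundingSpec, RoundingMode, str],
) -> FixedValue:
    """Multiply ``a * b`` into ``fmt_out`` with rounding and saturation.

    The exact integer product is formed first (no wraparound is possible:
    raws are Python integers), rounded by ``p_a + p_b - p_out`` bits with
    :func:`~fxpode.fixedpoint.round_raw`, then clamped to the output range.
    """
    fmt_out = _coerce_format(fmt_out)
    f = a.fmt.p + b.fmt.p - fmt_out.p
    if f < 0:
        raise ValueError("output format has more fraction bits than the product")
    prod = a.raw * b.raw
    return _saturate(round_raw(prod, f, rs), fmt_out)


def add(a: FixedValue, b: FixedValue) -> FixedValue:
    """Exact same-format addition; overflow saturates and sets the flag."""
    if a.fmt != b.fmt:
        raise ValueError(f"format mismatch: {a.fmt} vs {b.fmt}")
    return _saturate(a.raw + b.raw, a.fmt)


def sub(a: FixedValue, b: FixedValue) -> FixedValue:
    """Exact same-format subtraction; overflow saturates and sets the flag."""
    if a.fmt != b.fmt:
        raise ValueError(f"format mismatch: {a.fmt} vs {b.fmt}")
    return _saturate(a.raw - b.raw, a.fmt)


def mul_reference(
    a: FixedValue,
    b: FixedValue,
    fmt_out: Union[FixedFormat, str],
    mode: Union[RoundingMode, str, RoundingSpec],
    sr_draw: Optional[int] = None,
    sr_bits: int = 32,
) -> Fraction:
    """Independent oracle: the multiply's mathematical definition on rationals.

    Computes ``decode(a) * decode(b)`` exactly, applies the rounding mode's
    textbook definition (for SR, the comparator law with the *same* ``k``-bit
    draw ``sr_draw`` the implementation would use), and clamps to the output
    range.  Used only by tests; shares no code path with :func:`mul` beyond
    the format descriptors.
    """
    fmt_out = _coerce_format(fmt_out)
    m = mode.mode if isinstance(mode, RoundingSpec) else RoundingMode(mode)
    x = a.value * b.value
    eps = fmt_out.epsilon
    floor_mult = (x / eps).numerator // (x / eps).denominator  # floor(x / eps)
    resid = x / eps - floor_mult  # in [0, 1)
    if m is RoundingMode.RD or resid == 0:
        r = floor_mult
    elif m is RoundingMode.RN:
        r = floor_mult + (1 if resid >= Fraction(1, 2) else 0)
    else:
        if sr_draw is None:
            raise ValueError("SR reference needs the implementation's random draw")
        top = (resid.numerator << sr_bits) // resid.denominator
        r = floor_mult + (1 if sr_draw < top else 0)
    val = r * eps
    return max(fmt_out.min_value, min(fmt_out.max_value, val))
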