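"""Bit Error Distribution (BED) harness for atomic multiplies.

For a multiply case and rounding mode, draw operand pairs uniformly from the
exactly-representable grid of each input format, multiply with the engine
under test, and record the signed error against the exact product in units
of the output format's LSB (the absolute error times ``2**p_out``).  The
sign convention is ``fixed result - reference``, so truncation errors are
non-positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Union

import numpy as np

from . import arith
from .arith import MUL_CASES, MulCase
from .fixedpoint import FixedFormat, FixedValue, RoundingMode, RoundingSpec, _coerce_format
from .prng import Algorithm, GeneratorState

__all__ = ["BEDResult", "bed_run", "default_range", "sample_pairs"]


@dataclass
class BEDResult:
    """LSB-normalized multiply errors plus summary statistics."""

    case: MulCase
    mode: RoundingMode
    n: int
    errors: np.ndarray
    seed: int
    mean: float = field(init=False)
    sd: float = field(init=False)
    min: float = field(init=False)
    max: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.errors) != self.n:
            raise ValueError("error vector length must equal n")
        if self.n:
            self.mean = float(np.mean(self.errors))
            self.sd = float(np.std(self.errors, ddof=1)) if self.n > 1 else 0.0
            self.min = float(np.min(self.errors))
            self.max = float(np.max(self.errors))
        else:
            self.mean = self.sd = self.min = self.max = float("nan")

    def summary(self) -> dict:
        return {
            "case": self.case.name,
            "out": str(self.case.fmt_out),
            "mode": self.mode.value,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "seed": self.seed,
        }

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("error_lsb\n")
            for e in self.errors:
                fh.write(f"{float(e)}\n")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def default_range(fmt: FixedFormat) -> tuple[Fraction, Fraction]:
    """Operand range keeping wide-by-wide products representable.

    Signed formats with integer bits use ``[-2**(i/2), 2**(i/2)]`` (e.g.
    ``[-256, 256]`` for s16.15, ``[-16, 16]`` for s8.7); pure-fraction
    formats use their full range.
    """
    if fmt.signed and fmt.i > 0:
        half = Fraction(1 << (fmt.i // 2))
        return -half, half
    return fmt.min_value, fmt.max_value


def _raw_bounds(fmt: FixedFormat, lo: Fraction, hi: Fraction) -> tuple[int, int]:
    # ceil(lo * 2**p), floor(hi * 2**p)
    s = lo * (1 << fmt.p)
    lo_raw = -((-s.numerator) // s.denominator)
    s = hi * (1 << fmt.p)
    hi_raw = s.numerator // s.denominator
    lo_raw = max(lo_raw, fmt.raw_min)
    hi_raw = min(hi_raw, fmt.raw_max)
    if lo_raw > hi_raw:
        raise ValueError("empty operand range")
    return lo_raw, hi_raw


def _uniform_raw(g: GeneratorState, lo_raw: int, hi_raw: int) -> int:
    span = hi_raw - lo_raw + 1
    r = (g.next_u32() << 32) | g.next_u32()
    return lo_raw + r % span


def sample_pairs(
    fmt_a: Union[FixedFormat, str],
    fmt_b: Union[FixedFormat, str],
    lo,
    hi,
    n: int,
    g: GeneratorState,
) -> list[tuple[FixedValue, FixedValue]]:
    """Draw ``n`` operand pairs, each exactly representable in its format.

    Values are uniform on the format's ``2**-p`` grid restricted to
    ``[lo, hi]`` (clipped to the representable range), so conversion to the
    reference type is exact by construction.
    """
    fmt_a, fmt_b = _coerce_format(fmt_a), _coerce_format(fmt_b)
    lo, hi = Fraction(lo), Fraction(hi)
    ba, bb = _raw_bounds(fmt_a, lo, hi), _raw_bounds(fmt_b, lo, hi)
    return [
        (
            FixedValue(_uniform_raw(g, *ba), fmt_a),
            FixedValue(_uniform_raw(g, *bb), fmt_b),
        )
        for _ in range(n)
    ]


def bed_run(
    case: Union[MulCase, str],
    mode: Union[RoundingMode, str],
    n: int = 50_000,
    seed: int = 0,
    algorithm: Union[Algorithm, str] = Algorithm.KISS99,
    lo=None,
    hi=None,
    sr_bits=None,
) -> BEDResult:
    """Measure the bit error distribution of one multiply case.

    Per draw, the error is ``(rounded product - exact product) * 2**p_out``;
    this is computed in exact integer arithmetic before the single float
    conversion, so the recorded errors carry no double-rounding artifact.
    """
    if isinstance(case, str):
        case = MUL_CASES[case]
    mode = RoundingMode(mode)
    g = GeneratorState(algorithm, seed)
    rs = RoundingSpec(mode, rng=g if mode is RoundingMode.SR else None)
    if sr_bits is not None:
        rs.k = sr_bits

    lo_a, hi_a = default_range(case.fmt_a) if lo is None or hi is None else (Fraction(lo), Fraction(hi))
    lo_b, hi_b = default_range(case.fmt_b) if lo is None or hi is None else (Fraction(lo), Fraction(hi))
    ba = _raw_bounds(case.fmt_a, lo_a, hi_a)
    bb = _raw_bounds(case.fmt_b, lo_b, hi_b)

    f = case.shift
    scale = float(2.0 ** -f)
    errors = np.empty(n)
    for j in range(n):
        ra = _uniform_raw(g, *ba)
        rb = _uniform_raw(g, *bb)
        res = arith.mul(FixedValue(ra, case.fmt_a), FixedValue(rb, case.fmt_b), case.fmt_out, rs)
        # (res.raw << f) - ra*rb is the error in units of 2**-f output LSBs
        errors[j] = ((res.raw << f) - ra * rb) * scale
    return BEDResult(case=case, mode=mode, n=n, errors=errors, seed=seed)
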