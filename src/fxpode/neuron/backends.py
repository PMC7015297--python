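"""Arithmetic backends executing the shared solver expression tree.

Each backend supplies the same tiny operation vocabulary (constant-by-state
multiply, state-by-state multiply, add, subtract, threshold compare), so a
single algebraic definition of each solver runs unchanged over float64,
emulated float32 and fixed-point arithmetic; observed output differences are
then purely arithmetic error.  ``TraceBackend`` records the operation
sequence symbolically, which is how the "same expression tree" property is
asserted in tests.
"""

from __future__ import annotations

import numpy as np

from .. import arith
from ..fixedpoint import FixedValue, RoundingSpec

__all__ = ["FixedBackend", "FloatBackend", "TraceBackend"]


class FloatBackend:
    """binary64, or emulated binary32 when ``single`` is set.

    The binary32 contract rounds every elementary result to the nearest
    single-precision value; this is realized as a float64 operation followed
    by a cast, which is exact for products of binary32 values and matches
    native binary32 arithmetic up to double-rounding corner cases.
    """

    def __init__(self, single: bool = False) -> None:
        self.single = single
        self.sat_count = 0  # floats saturate to inf, never clamp

    def _fl(self, x: float) -> float:
        return float(np.float32(x)) if self.single else x

    def mul_cs(self, c: float, x: float) -> float:
        return self._fl(c * x)

    mul_ss = mul_cs

    def add(self, a: float, b: float) -> float:
        return self._fl(a + b)

    def sub(self, a: float, b: float) -> float:
        return self._fl(a - b)

    def ge(self, x: float, thr: float) -> bool:
        return x >= thr


class FixedBackend:
    """Fixed-point arithmetic via :mod:`fxpode.arith`, counting saturations."""

    def __init__(self, state_fmt, const_fmt, rs: RoundingSpec) -> None:
        self.state_fmt = state_fmt
        self.const_fmt = const_fmt
        self.rs = rs
        self.sat_count = 0

    def _track(self, r: FixedValue) -> FixedValue:
        if r.saturated:
            self.sat_count += 1
        return r

    def mul_cs(self, c: FixedValue, x: FixedValue) -> FixedValue:
        return self._track(arith.mul(c, x, self.state_fmt, self.rs))

    def mul_ss(self, a: FixedValue, b: FixedValue) -> FixedValue:
        return self._track(arith.mul(a, b, self.state_fmt, self.rs))

    def add(self, a: FixedValue, b: FixedValue) -> FixedValue:
        return self._track(arith.add(a, b))

    def sub(self, a: FixedValue, b: FixedValue) -> FixedValue:
        return self._track(arith.sub(a, b))

    def ge(self, x: FixedValue, thr: FixedValue) -> bool:
        return x.raw >= thr.raw


class TraceBackend:
    """Symbolic backend: results are tuples recording the operation tree."""

    def __init__(self) -> None:
        self.ops: list[tuple] = []
        self.sat_count = 0

    def _rec(self, op, a, b):
        node = (op, a, b)
        self.ops.append(op)
        return node

    def mul_cs(self, c, x):
        return self._rec("mul_cs", c, x)

    def mul_ss(self, a, b):
        return self._rec("mul_ss", a, b)

    def add(self, a, b):
        return self._rec("add", a, b)

    def sub(self, a, b):
        return self._rec("sub", a, b)

    def ge(self, x, thr) -> bool:
        return False
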