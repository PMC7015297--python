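"""Deterministic uniform generators used to drive stochastic rounding.

Three algorithms behind one contract:

``KISS99``
    Marsaglia's 1999 combination generator (multiply-with-carry pair,
    3-shift register, linear congruential), period about ``2**123``.
``LFSR33``
    A 33-bit maximum-cycle Galois LFSR with taps at bits 33 and 20
    (characteristic polynomial ``x**33 + x**20 + 1``); the state advances
    32 single-bit steps per draw and the output word is the low 32 bits of
    the state.
``RANQD1``
    The quick-and-dirty linear congruential recipe with Knuth/Lewis
    constants: ``x <- (1664525*x + 1013904223) mod 2**32``.

All generators yield 32-bit unsigned integers; a Box-Muller adapter supplies
standard normal variates for input dither.  Streams are fully determined by
``(algorithm, seed)``.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

__all__ = ["Algorithm", "GeneratorState", "LFSR33_TAP_MASK"]

_M32 = 0xFFFFFFFF
_M33 = 0x1FFFFFFFF

#: Galois tap mask for x**33 + x**20 + 1 (bits 33 and 20, 1-based).
LFSR33_TAP_MASK = (1 << 32) | (1 << 19)

# Marsaglia's published default component seeds for KISS99.
_KISS_DEFAULTS = (362436069, 521288629, 123456789, 380116160)

_RANQD1_A = 1664525
_RANQD1_C = 1013904223


class Algorithm(str, enum.Enum):
    KISS99 = "KISS99"
    LFSR33 = "LFSR33"
    RANQD1 = "RANQD1"


def lfsr33_step(state: int) -> int:
    """One single-bit Galois step of the 33-bit LFSR (taps 33 and 20)."""
    return (state >> 1) ^ (LFSR33_TAP_MASK if state & 1 else 0)


def _splitmix64(x: int) -> tuple[int, int]:
    """One step of splitmix64; used only to expand a user seed into words."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x, z ^ (z >> 31)


def seed_words(algorithm: Algorithm, seed: Optional[int]) -> tuple[int, int, int, int]:
    """Expand ``seed`` into the algorithm's initial state words.

    ``seed=None`` selects the published default constants (KISS99) or a fixed
    nonzero default (LFSR33/RANQD1).  The expansion guards the LFSR against
    the forbidden all-zero state and the KISS99 shift register against zero.
    """
    algorithm = Algorithm(algorithm)
    if algorithm is Algorithm.KISS99:
        if seed is None:
            return _KISS_DEFAULTS
        s, a = _splitmix64(seed)
        s, b = _splitmix64(s)
        z = (_KISS_DEFAULTS[0] ^ (a & _M32)) or _KISS_DEFAULTS[0]
        w = (_KISS_DEFAULTS[1] ^ (a >> 32)) or _KISS_DEFAULTS[1]
        jsr = (_KISS_DEFAULTS[2] ^ (b & _M32)) or _KISS_DEFAULTS[2]
        jcong = (_KISS_DEFAULTS[3] ^ (b >> 32)) & _M32
        return z, w, jsr, jcong
    if algorithm is Algorithm.LFSR33:
        if seed is None:
            state = 0x123456789 & _M33
        else:
            _, a = _splitmix64(seed)
            state = a & _M33
        if state == 0:
            raise ValueError("LFSR33 requires a nonzero 33-bit state")
        return state, 0, 0, 0
    # RANQD1
    state = (0 if seed is None else seed) & _M32
    return state, 0, 0, 0


class GeneratorState:
    """A deterministic 32-bit uniform generator.

    Parameters
    ----------
    algorithm
        One of :class:`Algorithm` (or its string name).
    seed
        Integer seed expanded into the component state words; ``None`` picks
        the algorithm's documented default state.
    """

    __slots__ = ("algorithm", "seed", "_s", "draws")

    def __init__(self, algorithm: Algorithm | str = Algorithm.KISS99,
                 seed: Optional[int] = None) -> None:
        self.algorithm = Algorithm(algorithm)
        self.seed = seed
        self._s = list(seed_words(self.algorithm, seed))
        self.draws = 0

    @property
    def state(self) -> tuple[int, ...]:
        return tuple(self._s)

    def next_u32(self) -> int:
        """Advance one step and return a uniform 32-bit unsigned integer."""
        s = self._s
        self.draws += 1
        if self.algorithm is Algorithm.KISS99:
            z, w, jsr, jcong = s
            z = (36969 * (z & 0xFFFF) + (z >> 16)) & _M32
            w = (18000 * (w & 0xFFFF) + (w >> 16)) & _M32
            mwc = ((z << 16) + w) & _M32
            jsr ^= (jsr << 17) & _M32
            jsr ^= jsr >> 13
            jsr ^= (jsr << 5) & _M32
            jcong = (69069 * jcong + 1234567) & _M32
            s[0], s[1], s[2], s[3] = z, w, jsr, jcong
            return ((mwc ^ jcong) + jsr) & _M32
        if self.algorithm is Algorithm.LFSR33:
            # 32 single-bit Galois steps per output: one step per draw would
            # leave successive words sharing 31 bits, which breaks pairwise
            # uses (Box-Muller) even though marginals stay uniform.
            st = s[0]
            for _ in range(32):
                st = (st >> 1) ^ (LFSR33_TAP_MASK if st & 1 else 0)
            s[0] = st
            return st & _M32
        # RANQD1
        s[0] = (_RANQD1_A * s[0] + _RANQD1_C) & _M32
        return s[0]

    def uniform_bits(self, k: int) -> int:
        """Top ``k`` bits of the next 32-bit output, ``1 <= k <= 32``."""
        if not (1 <= k <= 32):
            raise ValueError("need 1 <= k <= 32")
        return self.next_u32() >> (32 - k)

    def uniform(self) -> float:
        """Uniform float in ``[0, 1)`` from one 32-bit draw."""
        return self.next_u32() / 4294967296.0

    def gaussian(self) -> float:
        """Standard normal variate via Box-Muller on two uniform draws.

        Exactly two 32-bit draws are consumed per call and no spare is
        cached, so the stream position is a simple function of the call
        count (the compiled simulation kernel mirrors this convention).
        """
        u1 = (self.next_u32() + 1) / 4294967296.0  # (0, 1]
        u2 = self.next_u32() / 4294967296.0
        return math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)

    def spawn(self, offset: int) -> "GeneratorState":
        """Derived generator for ensemble run ``offset`` (seed = base + offset)."""
        base = 0 if self.seed is None else self.seed
        return GeneratorState(self.algorithm, base + offset)

    def __repr__(self) -> str:
        return f"GeneratorState({self.algorithm.value}, seed={self.seed}, draws={self.draws})"
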