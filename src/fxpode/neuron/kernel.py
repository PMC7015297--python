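"""Compiled simulation kernels (numba) for long fixed-timestep runs.

These kernels re-state the exact operation sequence of
:mod:`fxpode.neuron.solvers` on raw int64 values (fixed-point) or floats,
including the rounding laws, the per-event random-draw convention and the
saturation rule of the object layer.  Bit-for-bit parity between the two
engines is asserted by the test suite, so the kernels can be treated as a
fast transport for the same arithmetic rather than a reimplementation.

Conventions mirrored from the slow path:

- one 32-bit generator draw per stochastic rounding event, skipped entirely
  when the discarded field is zero;
- SR compares the top ``k`` residual bits against the top ``k`` bits of the
  draw (``k = f`` for full SR, capped at 32);
- the input current is re-quantized (round-to-nearest) into the working
  type each step when dither or a decaying input makes it time-varying;
- Gaussian dither uses Box-Muller on two uniform draws, no cached spare.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_fixed", "run_float"]

_M32 = np.int64(0xFFFFFFFF)


@njit(inline="always")
def _next_u32(alg, st):
    if alg == 0:  # KISS99
        z = (36969 * (st[0] & 0xFFFF) + (st[0] >> 16)) & _M32
        w = (18000 * (st[1] & 0xFFFF) + (st[1] >> 16)) & _M32
        mwc = ((z << 16) + w) & _M32
        jsr = st[2]
        jsr = jsr ^ ((jsr << 17) & _M32)
        jsr = jsr ^ (jsr >> 13)
        jsr = (jsr ^ ((jsr << 5) & _M32)) & _M32
        jcong = (69069 * st[3] + 1234567) & _M32
        st[0] = z
        st[1] = w
        st[2] = jsr
        st[3] = jcong
        return ((mwc ^ jcong) + jsr) & _M32
    elif alg == 1:  # LFSR33, taps 33 and 20; 32 Galois bit-steps per word
        s = st[0]
        for _ in range(32):
            if s & 1:
                s = (s >> 1) ^ 0x100080000
            else:
                s = s >> 1
        st[0] = s
        return s & _M32
    else:  # RANQD1
        s = (1664525 * st[0] + 1013904223) & _M32
        st[0] = s
        return s


@njit(inline="always")
def _gauss(alg, st):
    u1 = (_next_u32(alg, st) + 1.0) / 4294967296.0
    u2 = _next_u32(alg, st) / 4294967296.0
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)


@njit(inline="always")
def _round_fx(prod, f, rmode, kbits, alg, st):
    if rmode == 0:  # RD
        return prod >> f
    if rmode == 1:  # RN
        return (prod + (np.int64(1) << (f - 1))) >> f
    resid = prod & ((np.int64(1) << f) - 1)
    base = prod >> f
    if resid == 0:
        return base
    k = f if kbits == 0 else min(kbits, f)
    if k > 32:
        k = 32
    rand_k = _next_u32(alg, st) >> (32 - k)
    top = resid >> (f - k)
    if rand_k < top:
        return base + 1
    return base


@njit(inline="always")
def _clamp(x, lo, hi, sat):
    if x < lo:
        sat[0] += 1
        return lo
    if x > hi:
        sat[0] += 1
        return hi
    return x


@njit(inline="always")
def _mul(a, b, f, lo, hi, rmode, kbits, alg, st, sat):
    return _clamp(_round_fx(a * b, f, rmode, kbits, alg, st), lo, hi, sat)


@njit(inline="always")
def _add(a, b, lo, hi, sat):
    return _clamp(a + b, lo, hi, sat)


@njit
def _rhs_fx(v, u, Ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat):
    t = _mul(C[0], v, pcs, lo, hi, rmode, kbits, alg, st, sat)
    t = _add(t, C[4], lo, hi, sat)
    dv = _mul(t, v, pss, lo, hi, rmode, kbits, alg, st, sat)
    dv = _add(dv, C[5], lo, hi, sat)
    dv = _add(dv, -u, lo, hi, sat)
    dv = _add(dv, Ir, lo, hi, sat)
    w = _mul(C[3], v, pcs, lo, hi, rmode, kbits, alg, st, sat)
    w = _add(w, -u, lo, hi, sat)
    du = _mul(C[2], w, pcs, lo, hi, rmode, kbits, alg, st, sat)
    return dv, du


@njit
def _rhs_dot_fx(v, u, dv, du, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat):
    t = _mul(C[1], v, pcs, lo, hi, rmode, kbits, alg, st, sat)
    t = _add(t, C[4], lo, hi, sat)
    gv = _mul(t, dv, pss, lo, hi, rmode, kbits, alg, st, sat)
    gv = _add(gv, -du, lo, hi, sat)
    w = _mul(C[3], dv, pcs, lo, hi, rmode, kbits, alg, st, sat)
    w = _add(w, -du, lo, hi, sat)
    gu = _mul(C[2], w, pcs, lo, hi, rmode, kbits, alg, st, sat)
    return gv, gu


@njit
def _step_fx(solver, v, u, Ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat):
    if solver == 0:  # RK2 midpoint
        dv1, du1 = _rhs_fx(v, u, Ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        vm = _add(v, _mul(C[7], dv1, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        um = _add(u, _mul(C[7], du1, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        dv2, du2 = _rhs_fx(vm, um, Ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        v1 = _add(v, _mul(C[6], dv2, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        u1 = _add(u, _mul(C[6], du2, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        return v1, u1
    elif solver == 1:  # RK2 trapezoid
        dv1, du1 = _rhs_fx(v, u, Ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        vp = _add(v, _mul(C[6], dv1, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        up = _add(u, _mul(C[6], du1, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        dv2, du2 = _rhs_fx(vp, up, Ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        sv = _add(dv1, dv2, lo, hi, sat)
        su = _add(du1, du2, lo, hi, sat)
        v1 = _add(v, _mul(C[7], sv, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        u1 = _add(u, _mul(C[7], su, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        return v1, u1
    elif solver == 2:  # RK3 Heun
        dv1, du1 = _rhs_fx(v, u, Ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        v2 = _add(v, _mul(C[8], dv1, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        u2 = _add(u, _mul(C[8], du1, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        dv2, du2 = _rhs_fx(v2, u2, Ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        v3 = _add(v, _mul(C[9], dv2, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        u3 = _add(u, _mul(C[9], du2, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        dv3, du3 = _rhs_fx(v3, u3, Ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        v1 = _add(_add(v, _mul(C[10], dv1, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat),
                  _mul(C[11], dv3, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        u1 = _add(_add(u, _mul(C[10], du1, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat),
                  _mul(C[11], du3, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        return v1, u1
    else:  # two-derivative (Chan-Tsai variant)
        dv, du = _rhs_fx(v, u, Ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        gv, gu = _rhs_dot_fx(v, u, dv, du, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        y2v = _add(_add(v, _mul(C[7], dv, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat),
                   _mul(C[12], gv, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        y2u = _add(_add(u, _mul(C[7], du, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat),
                   _mul(C[12], gu, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        dv2, du2 = _rhs_fx(y2v, y2u, Ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        gv2, gu2 = _rhs_dot_fx(y2v, y2u, dv2, du2, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        v1 = _add(_add(_add(v, _mul(C[6], dv, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat),
                       _mul(C[13], gv, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat),
                  _mul(C[14], gv2, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        u1 = _add(_add(_add(u, _mul(C[6], du, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat),
                       _mul(C[13], gu, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat),
                  _mul(C[14], gu2, pcs, lo, hi, rmode, kbits, alg, st, sat), lo, hi, sat)
        return v1, u1


@njit
def run_fixed(solver, C, pss, pcs, lo, hi, thr, c_raw, d_raw, v0, u0,
              i_raw0, recompute_i, input_kind, i_base, decay, dither_sd, scale,
              rmode, kbits, alg, st, h, n_steps, spike_target,
              spikes, record, v_trace, u_trace, sat):
    """Fixed-point run; returns (number of spikes, steps executed)."""
    v = v0
    u = u0
    ns = 0
    i_cur = i_base
    n = 0
    while n < n_steps:
        if recompute_i:
            x = i_cur
            if dither_sd > 0.0:
                x = x + dither_sd * _gauss(alg, st)
            ir = np.int64(math.floor(x * scale + 0.5))
            if ir < lo:
                ir = lo
            elif ir > hi:
                ir = hi
            if input_kind == 1:
                i_cur = i_cur * decay
        else:
            ir = i_raw0
        v1, u1 = _step_fx(solver, v, u, ir, C, pss, pcs, lo, hi, rmode, kbits, alg, st, sat)
        if v1 >= thr:
            if ns < spikes.shape[0]:
                spikes[ns] = (n + 1) * h
            ns += 1
            v1 = c_raw
            u1 = _add(u1, d_raw, lo, hi, sat)
        v = v1
        u = u1
        if record:
            v_trace[n] = v / scale
            u_trace[n] = u / scale
        n += 1
        if spike_target > 0 and ns >= spike_target:
            break
    return ns, n


# ---------------------------------------------------------------------------
# Floating-point kernels (binary64, or emulated binary32 via cast-per-op)
# ---------------------------------------------------------------------------

@njit(inline="always")
def _fl(x, single):
    if single:
        return np.float64(np.float32(x))
    return x


@njit
def _rhs_fl(v, u, I, C, single):
    t = _fl(C[0] * v, single)
    t = _fl(t + C[4], single)
    dv = _fl(t * v, single)
    dv = _fl(dv + C[5], single)
    dv = _fl(dv - u, single)
    dv = _fl(dv + I, single)
    w = _fl(C[3] * v, single)
    w = _fl(w - u, single)
    du = _fl(C[2] * w, single)
    return dv, du


@njit
def _rhs_dot_fl(v, u, dv, du, C, single):
    t = _fl(C[1] * v, single)
    t = _fl(t + C[4], single)
    gv = _fl(t * dv, single)
    gv = _fl(gv - du, single)
    w = _fl(C[3] * dv, single)
    w = _fl(w - du, single)
    gu = _fl(C[2] * w, single)
    return gv, gu


@njit
def _step_fl(solver, v, u, I, C, single):
    if solver == 0:
        dv1, du1 = _rhs_fl(v, u, I, C, single)
        vm = _fl(v + _fl(C[7] * dv1, single), single)
        um = _fl(u + _fl(C[7] * du1, single), single)
        dv2, du2 = _rhs_fl(vm, um, I, C, single)
        v1 = _fl(v + _fl(C[6] * dv2, single), single)
        u1 = _fl(u + _fl(C[6] * du2, single), single)
        return v1, u1
    elif solver == 1:
        dv1, du1 = _rhs_fl(v, u, I, C, single)
        vp = _fl(v + _fl(C[6] * dv1, single), single)
        up = _fl(u + _fl(C[6] * du1, single), single)
        dv2, du2 = _rhs_fl(vp, up, I, C, single)
        v1 = _fl(v + _fl(C[7] * _fl(dv1 + dv2, single), single), single)
        u1 = _fl(u + _fl(C[7] * _fl(du1 + du2, single), single), single)
        return v1, u1
    elif solver == 2:
        dv1, du1 = _rhs_fl(v, u, I, C, single)
        v2 = _fl(v + _fl(C[8] * dv1, single), single)
        u2 = _fl(u + _fl(C[8] * du1, single), single)
        dv2, du2 = _rhs_fl(v2, u2, I, C, single)
        v3 = _fl(v + _fl(C[9] * dv2, single), single)
        u3 = _fl(u + _fl(C[9] * du2, single), single)
        dv3, du3 = _rhs_fl(v3, u3, I, C, single)
        v1 = _fl(_fl(v + _fl(C[10] * dv1, single), single) + _fl(C[11] * dv3, single), single)
        u1 = _fl(_fl(u + _fl(C[10] * du1, single), single) + _fl(C[11] * du3, single), single)
        return v1, u1
    else:
        dv, du = _rhs_fl(v, u, I, C, single)
        gv, gu = _rhs_dot_fl(v, u, dv, du, C, single)
        y2v = _fl(_fl(v + _fl(C[7] * dv, single), single) + _fl(C[12] * gv, single), single)
        y2u = _fl(_fl(u + _fl(C[7] * du, single), single) + _fl(C[12] * gu, single), single)
        dv2, du2 = _rhs_fl(y2v, y2u, I, C, single)
        gv2, gu2 = _rhs_dot_fl(y2v, y2u, dv2, du2, C, single)
        v1 = _fl(_fl(_fl(v + _fl(C[6] * dv, single), single) + _fl(C[13] * gv, single), single)
                 + _fl(C[14] * gv2, single), single)
        u1 = _fl(_fl(_fl(u + _fl(C[6] * du, single), single) + _fl(C[13] * gu, single), single)
                 + _fl(C[14] * gu2, single), single)
        return v1, u1


@njit
def run_float(solver, C, single, thr, c_val, d_val, v0, u0,
              i_val, recompute_i, input_kind, i_base, decay, dither_sd,
              alg, st, h, n_steps, spike_target,
              spikes, record, v_trace, u_trace):
    """Floating-point run; returns (number of spikes, steps executed)."""
    v = v0
    u = u0
    ns = 0
    i_cur = i_base
    n = 0
    while n < n_steps:
        if recompute_i:
            x = i_cur
            if dither_sd > 0.0:
                x = x + dither_sd * _gauss(alg, st)
            iw = _fl(x, single)
            if input_kind == 1:
                i_cur = i_cur * decay
        else:
            iw = i_val
        v1, u1 = _step_fl(solver, v, u, iw, C, single)
        if v1 >= thr:
            if ns < spikes.shape[0]:
                spikes[ns] = (n + 1) * h
            ns += 1
            v1 = c_val
            u1 = _fl(u1 + d_val, single)
        v = v1
        u = u1
        if record:
            v_trace[n] = v
            u_trace[n] = u
        n += 1
        if spike_target > 0 and ns >= spike_target:
            break
    return ns, n
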