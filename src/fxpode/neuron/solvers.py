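"""ESR-unrolled per-step updates for the four fixed-timestep solvers.

Each solver is written once, over the backend operation vocabulary, as the
explicit-solver-reduction (ESR) form of the named scheme applied to the
Izhikevich right-hand side.  The operation ordering follows two rules:
sub-unity constants stay in the unsigned fraction format and multiply
directly into state values, and stage increments are summed before the
single timestep-coefficient multiply so intermediates stay in the wide
format as long as possible.

Derivative evaluation (Horner form, 4 multiplies)::

    dv = (alpha*v + 5)*v + 140 - u + I
    du = a*(b*v - u)

The two-derivative solver additionally evaluates the time derivative of the
right-hand side along the flow (input held constant over the step)::

    gv = (beta*v + 5)*dv - du          with beta = 2*alpha = 0.08
    gu = a*(b*dv - du)
"""

from __future__ import annotations

import enum

__all__ = ["Solver", "SOLVER_STEPS", "step_algebra"]


class Solver(str, enum.Enum):
    RK2_MIDPOINT = "RK2_MIDPOINT"
    RK2_TRAPEZOID = "RK2_TRAPEZOID"
    RK3_HEUN = "RK3_HEUN"
    CHAN_TSAI = "CHAN_TSAI"


def _rhs(be, C, v, u, I):
    t = be.mul_cs(C["alpha"], v)
    t = be.add(t, C["five"])
    dv = be.mul_ss(t, v)
    dv = be.add(dv, C["c140"])
    dv = be.sub(dv, u)
    dv = be.add(dv, I)
    w = be.mul_cs(C["b"], v)
    w = be.sub(w, u)
    du = be.mul_cs(C["a"], w)
    return dv, du


def _rhs_dot(be, C, v, u, dv, du):
    # d/dt of the right-hand side along the flow, DC input
    t = be.mul_cs(C["beta"], v)
    t = be.add(t, C["five"])
    gv = be.mul_ss(t, dv)
    gv = be.sub(gv, du)
    w = be.mul_cs(C["b"], dv)
    w = be.sub(w, du)
    gu = be.mul_cs(C["a"], w)
    return gv, gu


def _step_rk2_midpoint(be, C, v, u, I):
    dv1, du1 = _rhs(be, C, v, u, I)
    vm = be.add(v, be.mul_cs(C["h2"], dv1))
    um = be.add(u, be.mul_cs(C["h2"], du1))
    dv2, du2 = _rhs(be, C, vm, um, I)
    v1 = be.add(v, be.mul_cs(C["h"], dv2))
    u1 = be.add(u, be.mul_cs(C["h"], du2))
    return v1, u1


def _step_rk2_trapezoid(be, C, v, u, I):
    dv1, du1 = _rhs(be, C, v, u, I)
    vp = be.add(v, be.mul_cs(C["h"], dv1))
    up = be.add(u, be.mul_cs(C["h"], du1))
    dv2, du2 = _rhs(be, C, vp, up, I)
    v1 = be.add(v, be.mul_cs(C["h2"], be.add(dv1, dv2)))
    u1 = be.add(u, be.mul_cs(C["h2"], be.add(du1, du2)))
    return v1, u1


def _step_rk3_heun(be, C, v, u, I):
    dv1, du1 = _rhs(be, C, v, u, I)
    v2 = be.add(v, be.mul_cs(C["h3"], dv1))
    u2 = be.add(u, be.mul_cs(C["h3"], du1))
    dv2, du2 = _rhs(be, C, v2, u2, I)
    v3 = be.add(v, be.mul_cs(C["h23"], dv2))
    u3 = be.add(u, be.mul_cs(C["h23"], du2))
    dv3, du3 = _rhs(be, C, v3, u3, I)
    v1 = be.add(be.add(v, be.mul_cs(C["h4"], dv1)), be.mul_cs(C["h34"], dv3))
    u1 = be.add(be.add(u, be.mul_cs(C["h4"], du1)), be.mul_cs(C["h34"], du3))
    return v1, u1


def _step_chan_tsai(be, C, v, u, I):
    # Two-derivative Runge-Kutta, two-stage "special" form: one f evaluation
    # plus the flow derivative g at the start point and at an interior stage.
    dv, du = _rhs(be, C, v, u, I)
    gv, gu = _rhs_dot(be, C, v, u, dv, du)
    y2v = be.add(be.add(v, be.mul_cs(C["h2"], dv)), be.mul_cs(C["hh8"], gv))
    y2u = be.add(be.add(u, be.mul_cs(C["h2"], du)), be.mul_cs(C["hh8"], gu))
    dv2, du2 = _rhs(be, C, y2v, y2u, I)
    gv2, gu2 = _rhs_dot(be, C, y2v, y2u, dv2, du2)
    v1 = be.add(
        be.add(be.add(v, be.mul_cs(C["h"], dv)), be.mul_cs(C["hh6"], gv)),
        be.mul_cs(C["hh3"], gv2),
    )
    u1 = be.add(
        be.add(be.add(u, be.mul_cs(C["h"], du)), be.mul_cs(C["hh6"], gu)),
        be.mul_cs(C["hh3"], gu2),
    )
    return v1, u1


SOLVER_STEPS = {
    Solver.RK2_MIDPOINT: _step_rk2_midpoint,
    Solver.RK2_TRAPEZOID: _step_rk2_trapezoid,
    Solver.RK3_HEUN: _step_rk3_heun,
    Solver.CHAN_TSAI: _step_chan_tsai,
}


def step_algebra(solver: Solver, be, C, v, u, I):
    """One unrolled solver step in the backend's arithmetic (no reset)."""
    return SOLVER_STEPS[Solver(solver)](be, C, v, u, I)
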