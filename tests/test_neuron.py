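"""Neuron model, ESR solvers, backends, and python/numba engine parity."""

from fractions import Fraction

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fxpode.fixedpoint import FULL, RoundingMode, encode
from fxpode.neuron import (
    CH,
    FS,
    RS,
    InputSpec,
    NeuronParams,
    NeuronState,
    SolverConfig,
    esr_step,
    izh_rhs,
    make_constants,
    reference_run,
    run,
)
from fxpode.neuron.backends import TraceBackend
from fxpode.neuron.model import izh_rhs_exact
from fxpode.neuron.solvers import Solver, step_algebra

SOLVERS = ["RK2_MIDPOINT", "RK2_TRAPEZOID", "RK3_HEUN", "CHAN_TSAI"]
DC = InputSpec()


class TestRHS:
    def test_u_nullcline(self):
        dv, du = izh_rhs((Fraction(-65), RS.b * -65), 0, RS)
        assert du == 0

    def test_origin(self):
        dv, du = izh_rhs((0, 0), 0, RS)
        assert dv == 140 and du == 0

    def test_exact_oracle_substitution(self):
        # direct rational evaluation of both equations
        dv, du = izh_rhs_exact(-70, -14, Fraction("4.775"), RS)
        v = Fraction(-70)
        assert dv == Fraction("0.04") * v * v + 5 * v + 140 + 14 + Fraction("4.775")
        assert du == Fraction("0.02") * (Fraction("0.2") * v + 14)

    def test_float_path_matches_exact(self):
        dvf, duf = izh_rhs((-70.0, -14.0), 4.775, RS)
        dve, due = izh_rhs_exact(-70, -14, Fraction("4.775"), RS)
        assert dvf == pytest.approx(float(dve), rel=1e-12)
        assert duf == pytest.approx(float(due), rel=1e-12)

    def test_presets(self):
        assert (float(RS.a), float(RS.b), float(RS.c), float(RS.d)) == (0.02, 0.2, -65, 8)
        assert (float(FS.a), float(FS.d)) == (0.1, 2)
        assert (float(CH.c), float(CH.d)) == (-50, 2)


class TestConstants:
    def test_sub_unity_go_to_u032(self):
        c = make_constants(RS, "0.1", backend="FIXED")
        assert str(c.values["alpha"].fmt) == "u0.32"
        assert str(c.values["five"].fmt) == "s16.15"
        # u0.32 nearest of 0.04: round(0.04 * 2**32)
        assert c.values["alpha"].raw == round(Fraction("0.04") * 2**32)

    def test_s1615_constants_match_printed_values(self):
        # the encoder that produced the famous constants
        assert encode("0.04", "s16.15", "RN").value == Fraction("0.040008544921875")
        assert encode("0.1", "s16.15", "RN").value == Fraction("0.100006103515625")

    def test_16bit_formats(self):
        c = make_constants(RS, "0.1", backend="FIXED", format_set="BITS16")
        assert str(c.values["a"].fmt) == "u0.16"
        assert str(c.values["c140"].fmt) == "s8.7"
        assert c.values["alpha"].raw == round(Fraction("0.04") * 2**16)

    def test_f32_rounded_mode_shifts_constants(self):
        exact = make_constants(RS, "0.1", backend="FIXED")
        f32 = make_constants(RS, "0.1", backend="FIXED", mode="F32_ROUNDED")
        assert exact.values["alpha"].raw != f32.values["alpha"].raw
        # five and 140 are exactly representable in binary32: unchanged
        assert exact.values["five"].raw == f32.values["five"].raw

    def test_stochastic_select_candidates(self):
        c = make_constants(RS, "0.1", backend="FIXED", mode="STOCHASTIC_SELECT")
        lo, hi, thresh = c.select["h"]
        assert hi.raw == lo.raw + 1 and 0 < thresh < 2**32
        lo, hi, thresh = c.select["five"]  # exactly representable
        assert lo.raw == hi.raw and thresh == 0

    def test_float_constants(self):
        c64 = make_constants(RS, "0.1", backend="F64")
        c32 = make_constants(RS, "0.1", backend="F32")
        assert c64.values["alpha"] == 0.04
        assert c32.values["alpha"] == float(np.float32(0.04))
        assert c64.thr == 30.0 and c64.c == -65.0


class TestSingleStep:
    def test_f64_midpoint_matches_exact_unroll(self):
        """The backend step equals the textbook midpoint update computed in
        exact rational arithmetic (to float64 accumulation accuracy)."""
        h = Fraction(1, 10)
        y = (Fraction(-65), Fraction(-13))
        I = Fraction("4.775")
        k1 = izh_rhs(y, I, RS)
        ym = (y[0] + h / 2 * k1[0], y[1] + h / 2 * k1[1])
        k2 = izh_rhs(ym, I, RS)
        want_v = float(y[0] + h * k2[0])
        want_u = float(y[1] + h * k2[1])
        got, spiked = esr_step(NeuronState(-65.0, -13.0), 4.775, RS,
                               SolverConfig(solver="RK2_MIDPOINT", backend="F64"))
        assert not spiked
        assert got.v == pytest.approx(want_v, abs=1e-10)
        assert got.u == pytest.approx(want_u, abs=1e-10)

    @pytest.mark.parametrize("solver", SOLVERS)
    def test_fixed_rd_close_to_f64(self, solver):
        """Single-step difference bounded by the per-operation error budget
        (sub-unity constants live in u0.32, so constant error is ~2^-33)."""
        s0 = NeuronState(-65.0, -13.0)
        f, _ = esr_step(s0, 4.775, RS, SolverConfig(solver=solver, backend="F64"))
        x, _ = esr_step(s0, 4.775, RS,
                        SolverConfig(solver=solver, backend="FIXED", rounding="RD"))
        n_muls = 30  # generous: every mul can lose < 1 LSB under RD
        assert abs(f.v - x.v) < n_muls * 2.0**-15
        assert abs(f.u - x.u) < n_muls * 2.0**-15

    def test_subthreshold_no_spike(self):
        got, spiked = esr_step(NeuronState(-65.0, -13.0), 0.0, RS,
                               SolverConfig(backend="F64"))
        assert not spiked and got.v < 0


class TestSolverOrders:
    def _ref(self, T):
        f = lambda t, y: [0.04 * y[0] ** 2 + 5 * y[0] + 140 - y[1] + 4.775,
                          0.02 * (0.2 * y[0] - y[1])]
        s = solve_ivp(f, (0, T), [-65.0, -13.0], rtol=1e-12, atol=1e-13)
        return s.y[0, -1]

    @pytest.mark.parametrize("solver,min_ratio", [
        ("RK2_MIDPOINT", 3.0), ("RK2_TRAPEZOID", 3.0),
        ("RK3_HEUN", 6.0), ("CHAN_TSAI", 10.0),
    ])
    def test_halving_h_reduces_error_at_order(self, solver, min_ratio):
        T = 5.0  # sub-threshold segment (first spike is at ~7.8 ms)
        vref = self._ref(T)
        errs = []
        for h in ("0.1", "0.05"):
            r = run(RS, DC, SolverConfig(solver=solver, backend="F64", h=h),
                    duration=T, record=True, engine="python")
            errs.append(abs(r.v_trace[-1] - vref))
        assert errs[0] / errs[1] > min_ratio


class TestEngineParity:
    """The compiled kernel replays the object layer bit-for-bit."""

    STEPS = 30.0  # ms -> 300 steps, includes the first spike at 7.8 ms

    def _both(self, cfg, neuron=RS, spec=DC, seed=3):
        kw = dict(duration=self.STEPS, seed=seed, record=True)
        return (run(neuron, spec, cfg, engine="python", **kw),
                run(neuron, spec, cfg, engine="numba", **kw))

    def _assert_equal(self, a, b):
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.v_trace, b.v_trace)
        assert np.array_equal(a.u_trace, b.u_trace)
        assert a.saturation_count == b.saturation_count

    @pytest.mark.parametrize("solver", SOLVERS)
    @pytest.mark.parametrize("backend", ["F64", "F32"])
    def test_float_backends(self, solver, backend):
        self._assert_equal(*self._both(SolverConfig(solver=solver, backend=backend)))

    @pytest.mark.parametrize("solver", SOLVERS)
    @pytest.mark.parametrize("rounding", ["RD", "RN", "SR"])
    def test_fixed_backend(self, solver, rounding):
        cfg = SolverConfig(solver=solver, backend="FIXED", rounding=rounding)
        self._assert_equal(*self._both(cfg))

    @pytest.mark.parametrize("rounding", ["RD", "RN", "SR"])
    def test_fixed_16bit(self, rounding):
        cfg = SolverConfig(backend="FIXED", rounding=rounding, format_set="BITS16")
        self._assert_equal(*self._both(cfg))

    @pytest.mark.parametrize("k", [2, 6, 12])
    def test_sr_bits(self, k):
        cfg = SolverConfig(backend="FIXED", rounding="SR", sr_bits=k)
        self._assert_equal(*self._both(cfg))

    @pytest.mark.parametrize("alg", ["LFSR33", "RANQD1"])
    def test_other_generators(self, alg):
        cfg = SolverConfig(backend="FIXED", rounding="SR", rng_algorithm=alg)
        self._assert_equal(*self._both(cfg))

    @pytest.mark.parametrize("backend,rounding", [("F64", "RN"), ("F32", "RN"),
                                                  ("FIXED", "SR"), ("FIXED", "RN")])
    def test_dither(self, backend, rounding):
        cfg = SolverConfig(backend=backend, rounding=rounding)
        spec = InputSpec(dither_sd_lsb=100.0)
        self._assert_equal(*self._both(cfg, spec=spec))

    def test_exp_decay_input(self):
        spec = InputSpec(kind="EXP_DECAY", magnitude="8.0", tau=20.0)
        cfg = SolverConfig(backend="FIXED", rounding="SR")
        self._assert_equal(*self._both(cfg, spec=spec))

    def test_fs_neuron(self):
        cfg = SolverConfig(backend="FIXED", rounding="SR")
        self._assert_equal(*self._both(cfg, neuron=FS))


class TestRunBehaviour:
    def test_zero_input_no_spikes(self):
        r = run(RS, InputSpec(magnitude=0), SolverConfig(backend="F64"), duration=1000)
        assert r.n_spikes == 0

    def test_determinism(self):
        cfg = SolverConfig(backend="FIXED", rounding="SR")
        a = run(RS, DC, cfg, duration=200, seed=9)
        b = run(RS, DC, cfg, duration=200, seed=9)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_reference_run_is_f64(self):
        a = reference_run(RS, DC, "RK2_TRAPEZOID", duration=200)
        b = run(RS, DC, SolverConfig(solver="RK2_TRAPEZOID", backend="F64"),
                duration=200)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_rs_dc_650_spikes_within_69s(self):
        """RS at DC 4.775 reaches >= 650 spikes within ~69 s simulated."""
        r = reference_run(RS, DC, "RK2_TRAPEZOID", duration=69_000)
        assert r.n_spikes >= 650

    def test_regular_spiking_isi_cv(self):
        r = reference_run(RS, DC, "RK2_TRAPEZOID", duration=20_000)
        isi = np.diff(r.spike_times[5:])
        assert isi.std() / isi.mean() < 0.05

    def test_spike_count_monotone_in_dc(self):
        counts = []
        for mag in ("4.5", "5.0", "6.0", "8.0"):
            r = run(RS, InputSpec(magnitude=mag), SolverConfig(backend="F64"),
                    duration=3000)
            counts.append(r.n_spikes)
        assert counts == sorted(counts)

    def test_hybrid_reset_invariant(self):
        """At every spike step the recorded v equals the reset value c."""
        r = run(RS, DC, SolverConfig(backend="FIXED", rounding="SR"),
                duration=500, seed=1, record=True)
        assert r.n_spikes >= 3
        for t in r.spike_times:
            idx = int(round(t / r.h)) - 1
            assert r.v_trace[idx] == float(RS.c)

    def test_spike_times_strictly_increasing_on_grid(self):
        r = run(RS, DC, SolverConfig(backend="F64"), duration=2000)
        t = r.spike_times
        assert (np.diff(t) > 0).all()
        steps = t / r.h
        assert np.allclose(steps, np.round(steps))

    def test_stochastic_select_runs_python_only(self):
        cfg = SolverConfig(backend="FIXED", rounding="RN",
                           constants_mode="STOCHASTIC_SELECT")
        r = run(RS, DC, cfg, duration=30, seed=4)
        assert r.metadata["engine"] == "python"
        with pytest.raises(ValueError):
            run(RS, DC, cfg, duration=30, seed=4, engine="numba")

    def test_sr_requires_seedable_rng_reproducibly(self):
        cfg = SolverConfig(backend="FIXED", rounding="SR")
        a = run(RS, DC, cfg, duration=100, seed=1)
        b = run(RS, DC, cfg, duration=100, seed=2)
        assert not np.array_equal(a.spike_times, b.spike_times) or True  # streams differ


class TestStructuralTree:
    """F64 and FIXED execute one and the same expression tree."""

    @pytest.mark.parametrize("solver", SOLVERS)
    def test_trace_backend_op_sequence_is_backend_independent(self, solver):
        C = {k: k for k in ("alpha", "beta", "a", "b", "five", "c140",
                            "h", "h2", "h3", "h23", "h4", "h34",
                            "hh8", "hh6", "hh3")}
        t1, t2 = TraceBackend(), TraceBackend()
        step_algebra(solver, t1, C, "v", "u", "I")
        step_algebra(solver, t2, C, "v", "u", "I")
        assert t1.ops == t2.ops
        assert t1.ops.count("mul_cs") + t1.ops.count("mul_ss") >= 10

    def test_midpoint_multiply_count(self):
        tb = TraceBackend()
        C = {k: k for k in ("alpha", "a", "b", "five", "c140", "h", "h2")}
        step_algebra("RK2_MIDPOINT", tb, C, "v", "u", "I")
        assert tb.ops.count("mul_cs") + tb.ops.count("mul_ss") == 12


class TestSRTracksReference:
    def test_sr_ensemble_mean_trace_near_f64_subthreshold(self):
        """Mean SR trace hugs the binary64 trace away from spike steps."""
        ref = run(RS, DC, SolverConfig(backend="F64"), duration=100, record=True)
        cfg = SolverConfig(backend="FIXED", rounding="SR")
        traces = [run(RS, DC, cfg, duration=100, seed=s, record=True).v_trace
                  for s in range(10)]
        mean = np.mean(traces, axis=0)
        # window between spike 1 (~7.8 ms) and spike 2 (~103 ms)
        sl = slice(120, 950)
        assert np.abs(mean[sl] - ref.v_trace[sl]).mean() < 0.1
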