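# fxpode

Reduced-precision fixed-point arithmetic with rounding control, and a
spiking-neuron ODE testbench for measuring what that arithmetic does to
simulation accuracy.

The package provides:

- **`fxpode.fixedpoint`** — generalized `<sign, i, p>` fixed-point formats
  (`s16.15`, `u0.32`, `s0.31`, `s8.7`, `u0.16`, … and arbitrary widths),
  exact encode/decode via rationals, and three rounding primitives:
  round-down (2's-complement truncation), round-to-nearest (ties up) and
  stochastic rounding, including the reduced-bit-width SR comparator and the
  mathematically equivalent add-then-truncate formulation.
- **`fxpode.prng`** — the three deterministic uniform generators used to
  drive SR (KISS99, a 33-bit LFSR with taps 33/20, and the `ranqd1` linear
  congruential recipe) plus a Box–Muller Gaussian adapter for input dither.
- **`fxpode.arith`** — mixed-format saturating multiplication with a
  full-precision intermediate product and selectable rounding; the five
  32-bit cases (`s16.15×s16.15`, `s16.15×s0.31`, `s16.15×u0.32`,
  `u0.32×u0.32`, `u0.32×s0.31`) and their 16-bit equivalents are registered
  configurations of one generic engine, plus an exact-rational reference
  multiplier used as the test oracle.
- **`fxpode.bed`** — the Bit Error Distribution harness: uniformly sampled
  exactly-representable operand pairs, errors normalized to output LSBs.
- **`fxpode.neuron`** — the Izhikevich neuron (RS/FS/CH presets) with four
  unrolled fixed-timestep solvers (RK2 midpoint, RK2 trapezoid, RK3 Heun,
  and a two-derivative Chan–Tsai-style 2-stage scheme), runnable over
  binary64, emulated binary32, and fixed-point backends (32-bit
  `s16.15`/`u0.32` or 16-bit `s8.7`/`u0.16` format sets) with RD/RN/SR
  rounding on every multiply. A plain-Python object layer is the reference
  implementation; numba kernels replay it bit-for-bit for long runs (parity
  is asserted in the test suite).
- **`fxpode.experiments`** — spike-lag analysis against the binary64
  arithmetic reference, SR ensembles, SR-bit-width sweeps, Gaussian input
  dither sweeps and membrane-trace comparison.

## CLI

The console script `fxpode` exposes the testbench. Examples:

```sh
# bit-error distribution of an atomic multiply
fxpode bed --case s16.15xs16.15 --mode SR --n 50000 --seed 1 --out hist.csv

# one simulation: fixed-point, stochastic rounding with a 6-bit comparator
fxpode simulate --neuron RS --solver rk2mid --backend fixed --rounding SR \
    --sr-bits 6 --h 0.1 --input dc:4.775 --spikes 650 --seed 1 --out run.json

# spike-lag of round-down fixed point vs the binary64 reference
fxpode lag --neuron RS --solver rk2mid --backend fixed --rounding RD \
    --spikes 650 --out lag.csv

# SR ensemble (mean +/- SD of per-spike lag over R seeded runs)
fxpode ensemble --neuron FS --solver rk2trap --spikes 650 -R 10 --out ens.csv

# sweeps
fxpode sweep-bits --neuron RS --solver rk3heun --spikes 650 --k-list 2,4,6,12,FULL
fxpode sweep-dither --neuron RS --backend float --levels 0,1,10,100,1000,10000

# membrane trace around the third spike
fxpode trace --backend fixed --rounding RD --window 190,215 --out tr.csv
```

Every command accepts `--config FILE` with `key = value` lines supplying
option defaults. `scripts/plot_panels.py` turns the CSVs into figure-style
panels (histograms, lag series, error-bar sweeps, traces).

## Notes on conventions

- Rounding operates on exact integers (raw values, full-precision products);
  rationals appear only at encode/decode boundaries. Encoding out of range
  raises; saturation is a property of the multiply/add stage and is counted.
- One 32-bit generator draw is consumed per stochastic-rounding event; a
  zero residual consumes no draw. k-bit SR compares the top k residual bits
  with the top k bits of the draw.
- Spike lag is `t_test(n) − t_ref(n)` (positive = lag, negative = lead),
  with NaN marking runs that never produced spike `n`.
- Ensemble SDs use the sample (n−1) denominator; ensemble run r uses seed
  `base_seed + r`.
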