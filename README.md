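# stdpsim

A vectorized, plasticity-centric simulator for spiking neural networks,
with the statistical machinery needed to compare simulations of differing
numerical precision.

## Who this is for

Studies of synaptic plasticity need simulations that resolve milliseconds
(the width of an STDP window) yet run for hours to days of simulated time
(the timescale of long-term plasticity). For medium-sized networks of
10^4–10^5 neurons, simulation *speed* — not neuron count — is the binding
constraint, which motivates forward Euler integration, single-precision
arithmetic, whole-population array updates, and event-based synaptic
plasticity. This package implements that design in scientific Python and
adds the analysis tools to quantify what the speed/precision trade-off
does to network statistics.

## What is inside

- **Neurons** — leaky integrate-and-fire with conductance-based (COBA) or
  current-based (CUBA) synapses, advanced by forward Euler at a fixed step
  (default Δt = 0.1 ms), plus an adaptive embedded Runge–Kutta–Fehlberg
  4(5) reference integrator for precision studies.
- **Plasticity** — trace-based STDP: a synaptic trace z obeys
  dz/dt = −z/τ + S(t), so an exponential-window pair rule

      Δw = +λ A₊ z₊(t)  at postsynaptic spikes,
      Δw = −λ A₋ z₋(t)  at (delayed) presynaptic spike arrivals,

  is exact and purely event-driven. Also: the minimal all-to-all triplet
  rule (potentiation gated by a slow postsynaptic trace), power-law weight
  dependence (additive → multiplicative), a brute-force pairwise oracle,
  and a NEST-style retrospective batch-update policy with an axonal vs
  dendritic delay switch.
- **Connectivity** — sparse weight matrices with forward and backward
  views over one shared weight store, uniform-delay ring buffers, and
  Matrix Market I/O.
- **Poisson input** — a stride-based generator for homogeneous Poisson
  populations in which every random number yields exactly one spike, and a
  per-neuron Poisson-count drive (the `poisson_generator` idiom).
- **Model zoo** — builders for three standard balanced-network benchmarks:
  the Vogels–Abbott COBA network (4000 cells, ~3.2×10⁵ synapses), a
  10,000-cell Brunel-type CUBA network (~10⁷ synapses, optionally with
  multiplicative STDP on E→E), and a 25,000-cell COBA network (~3.4×10⁷
  synapses, triplet STDP on E→E) operating near 3 Hz.
- **Statistics** — per-neuron rates, pooled inter-spike intervals, CV ISI,
  and two-sample Kolmogorov–Smirnov comparison (D statistic and asymptotic
  p), including repeated-window mean-D comparisons.
- **Run-time model** — T(n) = α/n + β·⌈log₂n⌉ + γ·(n−1)/n (or the ring
  variant β·(n−1)) for strong-scaling analysis: evaluation, RMS fitting
  with nonnegativity constraints, and the plasticity overhead ratio
  χ = (T_PL − T_NP)/T_NP.

## Worked example

Generate 100 s of spikes from 1000 Poisson units at 5 Hz and check the
first- and second-order statistics:

```python
from stdpsim import PoissonPopulation
from stdpsim.stats import isi_and_cv

pop = PoissonPopulation(n_units=1000, rate=5.0, dt=0.1, rng_seed=1)
raster = pop.generate_raster(100.0)
isis, cvs = isi_and_cv(raster)
print(f"{len(raster)} spikes, mean rate {len(raster) / (1000 * 100.0):.4f} Hz, "
      f"mean CV ISI {cvs.mean():.4f}")
```

prints

```
501230 spikes, mean rate 5.0123 Hz, mean CV ISI 0.9958
```

i.e. the stride generator reproduces the nominal 5 Hz rate and the
CV ISI ≈ 1 signature of a Poisson process. A network example from the
shell:

```bash
stdpsim simulate --model vogels_abbott --duration 2 --seed 3 --out out/
```

```
[stdpsim] t = 1.0 s (65739 spikes so far)
[stdpsim] t = 2.0 s (129849 spikes so far)
exc: 103325 spikes, mean rate 16.145 Hz
inh: 26524 spikes, mean rate 16.578 Hz
outputs written to out
```

The excitatory and inhibitory populations settle into the balanced
asynchronous-irregular state at ~16 Hz. Raster files
(`time_in_seconds neuron_id` per line) and the fully resolved
configuration are written to `out/` (add `--save-weights` for the final
Matrix Market weight matrices); `stdpsim stats` and `stdpsim compare`
analyze such rasters from any simulator, and
`stdpsim fit-runtime --csv timings.csv` fits the scaling model to
(cores, run time) measurements.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the stride-based Poisson generator at the published benchmark
setup (1000 units, 5 Hz, 100 s, Δt = 0.1 ms) and writes the measured mean
per-unit firing rate in Hz to the JSON file. The broader desk-scale
reproductions (balanced-network operating rates, the Euler-vs-RKF45
precision comparison, and the oracle/property checks) live in
`tests/test_acceptance.py`.

See `docs/methods.md` for the model equations, update-order semantics,
parameter provenance, and known limitations.
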