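# Methods

## Neuron model and integration

All neurons are leaky integrate-and-fire units. Voltages are in mV, time
constants in ms, and synaptic conductances in units of the leak
conductance, so the conductance-based (COBA) subthreshold equation is

    τ_m dv/dt = (v_rest − v) + g_e (E_e − v) + g_i (E_i − v) + I_bias

and the current-based (CUBA) equation

    τ_m dv/dt = (v_rest − v) + g_e − g_i + I_bias

with I_bias the bias current times the membrane resistance (200 pA through
a 10 nS leak ↔ 20 mV). Synaptic variables decay as g ← g·exp(−Δt/τ_syn)
each step — the exact solution rather than an Euler step — for
unconditional stability and consistency with the plasticity traces.

The production integrator is forward Euler at fixed Δt (default 0.1 ms).
The threshold test uses ≥ (a tie fires); a membrane already at or above
threshold on entry to a step fires even if the leak term would pull it
back below within that step. Reset clamps v to v_reset; refractoriness is
an integer counter of round(t_ref/Δt) steps during which the neuron
neither integrates nor fires. Floating-point precision (32/64-bit) is a
global engine setting; 32-bit is the performance default, 64-bit the
oracle setting.

The reference integrator is an embedded Runge–Kutta–Fehlberg 4(5) with
adaptive sub-stepping inside each Δt. Error control uses the max-norm of
the embedded error estimate across all neurons and state variables
against a local tolerance (default 1e-8; the precision-study tests use
1e-6, still orders of magnitude below the Euler error). Threshold and
reset are applied on the Δt grid so spike semantics match the Euler path
exactly; step-size underflow raises an error naming the worst neuron.
Because balanced networks amplify microscopic perturbations
exponentially, Euler and reference runs (or 32- vs 64-bit runs) diverge
spike-by-spike; they are compared at the level of rate/ISI/CV-ISI
distributions (below).

## Update order and delay semantics

Each step t (time t·Δt) executes, in order: (1) deliver spikes due from
the delay ring buffers and add synaptic weights into the target fields,
(2) plasticity on-pre for the delivered spikes, (3) evolve all neuron
groups and collect new spikes (Poisson groups draw here), (4) plasticity
on-post for the new spikes, (5) register the step's spikes in all traces
and decay the traces, (6) enqueue new spikes into the delay buffers,
(7) record.

Trace increments happen at stage 5, so a weight update at stage 2 or 4
sees spikes from strictly earlier steps only. Consequences:

- Delays are axonal: a presynaptic spike acts at the synapse
  delay/Δt ≥ 1 steps after firing, whereas a postsynaptic spike acts
  immediately. When two connected neurons fire in the same step, the
  postsynaptic spike reaches the synapse first (it enters the depression
  trace that the later pre arrival reads).
- Exact zero-lag pairs at the synapse (a postsynaptic spike in the very
  step a presynaptic spike arrives) contribute nothing to either branch
  of the STDP window. The brute-force pairwise oracle implements the same
  strict-inequality convention, which is what makes oracle equivalence
  exact rather than approximate.

One RNG stream is created per population from (seed, population index),
so recorder configuration or unrelated populations never perturb a
population's randomness; identical seed and configuration give
bit-identical rasters in both precisions.

## Plasticity

A synaptic trace obeys dz/dt = −z/τ + S(t); continuous mode multiplies by
exp(−Δt/τ) every step, event-based mode decays lazily with the closed
form between events. Both agree to float accuracy whenever read;
continuous is the default (the event path is kept behind a flag because
its scattered updates defeat vectorization at network scale).

Pair STDP with window W(s) = A₊e^{−s/τ₊} (s>0), −A₋e^{s/τ₋} (s<0) is
applied all-to-all through the traces: depression on presynaptic arrival
(reading the postsynaptic trace via the forward view), potentiation on
postsynaptic firing (reading the presynaptic trace via the backward
view), plus optional non-Hebbian per-spike terms a_pre/a_post. Weight
dependence follows the power-law family — potentiation × (1−w/w_max)^μ,
depression × α(w/w_max)^μ — so μ=0 is additive with asymmetry α and μ=1
multiplicative. Weights are clipped to [w_min, w_max] after every update
(w_min = 0 by default).

The triplet rule adds slow traces: on pre arrival
Δw = −λ z₋(t)(A₂₋ + A₃₋ z_x^pre(t)), on post firing
Δw = +λ z₊(t)(A₂₊ + A₃₊ z_y^post(t)), with the slow traces read just
before their own increment. Defaults are the minimal all-to-all
visual-cortex fit of the Pfister–Gerstner triplet model (A₂₊=0,
A₂₋=7·10⁻³, A₃₊=6.2·10⁻³, A₃₋=0; τ₊=16.8 ms, τ₋=33.7 ms, τ_x=101 ms,
τ_y=114 ms); amplitudes are on a normalized weight scale and multiplied
by the learning rate. A₃=0 reduces the rule exactly to pair STDP.

The retrospective policy mirrors the NEST approach: nothing is updated at
postsynaptic spikes; each neuron keeps a bounded history of recent firing
times, and at the next presynaptic arrival all deferred post-triggered
updates are replayed in time order with presynaptic trace values
reconstructed on the fly, followed by the arrival's depression. Replay
windows are half-open ([previous arrival, current arrival)), which
reproduces the immediate policy's strict zero-lag convention, so under
axonal semantics the two policies produce identical weights (to float
tolerance) — including under clipping and weight dependence, because the
replay applies updates in the same temporal order. The policy's
`dendritic` switch instead books post spikes at the synapse delay-late
and pre spikes delay-early, which flips the sign class of pairs closer
than the delay — the mechanism behind cross-simulator weight-distribution
differences. Evicted history entries are folded into a compressed trace
so depression stays exact; a replay that would need evicted entries
raises an error advising a larger buffer.

## Poisson generation

The stride generator fills the (unit × time-step) grid column by column:
with per-cell probability q = rate·Δt, strides x ~ Exponential(mean 1/q)
in cell units are drawn from the carried-over position; every landing
below N emits one spike at unit ⌊position⌋, and a stride crossing N
carries into the next step. Every random number yields exactly one spike
(the implementation asserts draws = spikes + 1 pending). Strides are
continuous exponentials floored to cells — statistically equivalent to a
geometric-integer variant at q ≪ 1 and simpler carry semantics. The
algorithm requires q < 1 and refuses otherwise. `generate_raster`
vectorizes the same recursion over the whole duration via one cumulative
sum (identical spikes and carry as stepping; it may consume extra random
numbers beyond the final carry, so mixed stepwise/vectorized use is
reproducible per call, not across the boundary). A per-cell Bernoulli(q)
brute-force generator is included as the independent statistical oracle,
and `PoissonCountInput` provides per-neuron independent Poisson event
counts (no q < 1 restriction) for strong external drives.

## Benchmark networks and parameter provenance

*Vogels–Abbott* (COBA, 3200 E + 800 I, p = 0.02, ~3.2×10⁵ synapses,
0.8 ms delay, 60 s default): the canonical PyNN-lineage parameter set
(τ_m=20 ms, v_rest=v_reset=−60 mV, v_thr=−50 mV, t_ref=5 ms, E_e=0,
E_i=−80 mV, τ_e=5 ms, τ_i=10 ms, w_e=0.4 and w_i=5.1 leak units) plus a
constant 200 pA-equivalent bias (20 mV) to prevent the self-sustained
state from dying out. Initial potentials uniform in [−60, −50) mV. This
configuration runs at ≈16–17 Hz.

*Brunel network* (CUBA, 8000 E + 2000 I, ε = 0.1, ~10⁷ synapses): the
classic sparsely connected random network with normalized voltage scale
(rest/reset 0, θ = 20 mV, τ_m = 20 ms, t_ref = 2 ms), unit EPSP peak
J = 0.1 mV (exponential current synapses, τ_syn = 0.5 ms; the synaptic
amplitude is computed from the closed-form PSP peak), inhibition g = 5
times stronger, and per-neuron external Poisson drive at rate
η·ν_thr·C_E with η = 2. With delays set to 0.8 ms and uniform initial
weights this reproduces the ≈43 Hz operating rate without any tuning.
The plastic variant attaches multiplicative (μ=1) STDP to E→E with
τ± = 20 ms, asymmetry α = 2.02, w_max = 3J and λ = 10⁻² (λ→0 for
statistics comparisons); α = 1 destabilizes the network at λ = 10⁻²,
confirming the depression-dominated asymmetry of the example lineage
this network follows.

*25k network* (COBA, 20000 E + 5000 I): E→E at p = 0.05 (~2×10⁷
synapses) carries triplet STDP; the remaining blocks share p = 0.0622 so
the total is ~3.4×10⁷. The published description of this network's
constants is not reproduced here, so the weights and drive are a
reconstruction pinned once to the published operating point (mean
population rate 3 Hz): VA neuron constants, w_EE=w_EI=0.05,
w_IE=w_II=0.5, external drive from 5000 stride-Poisson units at 10 Hz
connected with p = 0.05 at w = 0.15, triplet learning rate 0.05 (the
normalized amplitudes times the E→E weight scale). During calibration the
operating curve was deliberately flattened (weak recurrent excitation,
stronger feed-forward drive) because a strongly recurrent variant sat
near a bifurcation where ±5% in the E←I weight flipped the network
between ~2 Hz and ~20 Hz states. Every constant is exposed in the builder
and the spec/config dump. Measured: 3.03 Hz across seeds with plasticity
active.

## Statistics

Rates are spike counts per unit in [t0, t1) divided by the window length
(silent units report 0). ISIs are within-unit successive differences
pooled over the population; CV ISI is per-unit (std/mean, population
normalization) for units with ≥3 spikes. The two-sample
Kolmogorov–Smirnov test uses the asymptotic p-value (sample sizes here
are in the thousands); K-S always runs on unbinned data, histograms
(Freedman–Diaconis default) are for reporting only. Repeated-window
comparisons split a span into equal disjoint windows and report mean ± SD
of D. Note the pooled-ISI K-S is extremely sensitive at these sample
sizes — even two windows of one run differ "significantly" — so
cross-integrator equivalence is asserted on rate and CV-ISI
distributions, matching how such comparisons are interpreted in the
benchmarking literature.

## Run-time model

T(n) = α/n + β·⌈log₂n⌉ + γ·(n−1)/n (recursive-doubling/Bruck exchanges)
or T(n) = α/n + β·(n−1) + γ·(n−1)/n (ring), with α, β, γ ≥ 0. The model
is linear in the parameters, so the RMS fit is solved exactly by bounded
linear least squares; a log-space objective (nonlinear, for wide dynamic
ranges) and single-parameter refits (e.g. only α, transferring β, γ
between codes) are provided. The package evaluates and fits the model on
user-supplied timing data only — it does not measure wall-clock scaling
itself, and no timing claims are tested.

## What the tests do and do not establish

The acceptance suite reproduces desk-scale, hardware-independent
quantities: the Poisson generator's rate/count/CV-ISI/ISI laws, the
~43 Hz Brunel and ~3 Hz 25k operating points (shortened to a few
simulated seconds after discarding the initial transient; the rate
estimates are population-averaged and stable at these durations), the
Euler-vs-RKF45 rate-distribution equivalence on the Vogels–Abbott
network (per-neuron rates are quenched by the shared connectivity, which
is why the K-S p-value is robustly large), and exact equivalences
(pairwise oracle, trace modes, propagation against a dense oracle,
triplet degeneracy, immediate vs retrospective policies, run-time-model
recovery, K-S null calibration, bit-reproducibility). Wall-clock
results — absolute speed, speed-ups, scaling curves, sync-time
decompositions — are hardware-bound and out of scope.

Known limitations: no exact spike-time interpolation within a step; no
per-synapse heterogeneous delays (one delay per connection object); the
stride generator does not support heterogeneous or time-varying rates;
triplet STDP is implemented to triplet order only (no higher-order
terms); no distributed/MPI execution. The 25k network's constants are a
calibrated reconstruction, not the published table, so only its stated
structure and operating rate — not its detailed dynamics — should be
considered reproduced.
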