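"""The time-stepped simulation loop.

The engine ties neuron groups, Poisson inputs, delayed sparse connections
and plasticity rules together with a fixed, documented update order.  For
each step t (simulated time t*dt):

1. deliver delayed spikes: for every connection, pop the spikes due this
   step from its delay buffer and propagate them into the target field;
2. plasticity on-pre for the delivered spikes;
3. evolve all neuron-group states and collect new spikes (Poisson groups
   draw their spikes here);
4. plasticity on-post for the new spikes;
5. register the step's spikes in the traces and decay all traces;
6. enqueue new spikes into the outgoing delay buffers;
7. record.

Because trace increments happen at stage 5, an update at stage 2 or 4
only ever sees spikes from strictly earlier steps.  Together with the
delay buffers this realizes axonal delay semantics: when two connected
neurons fire in the same step, the postsynaptic spike acts at the synapse
before the presynaptic one arrives.

Reproducibility: every population owns one RNG stream seeded from
(config seed, population index), so recorder configuration or group
internals never perturb another population's randomness, and identical
seed + config give bit-identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import DelayBuffer, SparseWeightMatrix, propagate
from .neurons import (
    LIFParams,
    NeuronGroupState,
    StateCorruptionError,
    evolve_coba_euler,
    evolve_cuba_euler,
    reference_step,
)
from .poisson import PoissonCountInput, PoissonPopulation
from .raster import SpikeRaster

__all__ = [
    "EngineConfig",
    "NeuronGroup",
    "PoissonGroup",
    "PoissonDrive",
    "Connection",
    "Network",
    "SimulationResult",
    "run",
    "vectorized_state_update",
]


@dataclass
class EngineConfig:
    """Global simulation settings.

    dt and delay in ms, duration in seconds.  ``precision`` selects 32- or
    64-bit floating point state (32-bit is the performance default; use
    64-bit for oracle-grade runs).
    """

    dt: float = 0.1
    duration: float = 1.0
    precision: int = 32
    seed: int = 1
    delay: float = 0.8
    progress: bool = False
    integrator: str = "euler"  # euler | rkf45
    rkf_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.delay < self.dt:
            raise ValueError("delay must be >= dt")
        if self.precision not in (32, 64):
            raise ValueError("precision must be 32 or 64")
        if self.integrator not in ("euler", "rkf45"):
            raise ValueError("integrator must be 'euler' or 'rkf45'")

    @property
    def dtype(self):
        return np.float32 if self.precision == 32 else np.float64

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / (self.dt * 1e-3)))

    @property
    def delay_steps(self) -> int:
        return int(round(self.delay / self.dt))


@dataclass
class Counters:
    """Instrumentation: vectorized whole-array updates vs per-spike work."""

    vector_updates: int = 0
    spike_events: int = 0


class NeuronGroup:
    """A population of LIF neurons sharing one parameter set."""

    def __init__(
        self,
        name: str,
        n: int,
        params: LIFParams,
        model: str = "coba",
        v_init: tuple[float, float] | None = None,
    ) -> None:
        if model not in ("coba", "cuba"):
            raise ValueError("model must be 'coba' or 'cuba'")
        self.name = name
        self.n = int(n)
        self.params = params
        self.model = model
        self.v_init = v_init  # uniform (low, high) initial membrane potential
        self.state: NeuronGroupState | None = None
        self.rng: np.random.Generator | None = None

    def initialize(self, dtype, rng: np.random.Generator) -> None:
        self.rng = rng
        self.state = NeuronGroupState.zeros(self.n, self.params, dtype)
        if self.v_init is not None:
            lo, hi = self.v_init
            self.state.v = rng.uniform(lo, hi, self.n).astype(dtype)

    def evolve(self, dt: float, integrator: str, rkf_tol: float) -> np.ndarray:
        if integrator == "rkf45":
            reference_step(self.state, self.params, dt, rkf_tol, coba=self.model == "coba")
        elif self.model == "coba":
            evolve_coba_euler(self.state, self.params, dt)
        else:
            evolve_cuba_euler(self.state, self.params, dt)
        return self.state.spiked


class PoissonGroup:
    """Source-only population emitting homogeneous Poisson spikes
    (stride algorithm; see :mod:`stdpsim.poisson`)."""

    def __init__(self, name: str, n: int, rate: float) -> None:
        self.name = name
        self.n = int(n)
        self.rate = float(rate)
        self.pop: PoissonPopulation | None = None

    def initialize(self, dt: float, rng_seed) -> None:
        self.pop = PoissonPopulation(self.n, self.rate, dt, rng_seed)

    def evolve(self) -> np.ndarray:
        return self.pop.next_step_spikes()


@dataclass
class PoissonDrive:
    """Per-neuron independent Poisson input events injected directly into a
    target field (the poisson_generator idiom of event-based simulators)."""

    target: str
    rate: float
    weight: float
    target_field: str = "g_exc"
    input: PoissonCountInput | None = None


@dataclass
class Connection:
    """Delayed sparse connection between two named populations."""

    source: str
    target: str
    matrix: SparseWeightMatrix
    target_field: str = "g_exc"  # g_exc (excitatory) or g_inh (inhibitory)
    plasticity: object | None = None
    delay_buffer: DelayBuffer | None = None
    name: str = ""


class Network:
    """An assembled network: named groups plus connections and drives."""

    def __init__(self) -> None:
        self.groups: dict[str, NeuronGroup | PoissonGroup] = {}
        self.connections: list[Connection] = []
        self.drives: list[PoissonDrive] = []

    def add_group(self, group) -> None:
        if group.name in self.groups:
            raise ValueError(f"duplicate group name {group.name!r}")
        self.groups[group.name] = group

    def add_connection(self, conn: Connection) -> None:
        for end in (conn.source, conn.target):
            if end not in self.groups:
                raise ValueError(f"unknown group {end!r}")
        if isinstance(self.groups[conn.target], PoissonGroup):
            raise ValueError("Poisson groups cannot receive connections")
        m = conn.matrix
        if m.n_pre != self.groups[conn.source].n or m.n_post != self.groups[conn.target].n:
            raise ValueError("matrix shape does not match population sizes")
        if not conn.name:
            conn.name = f"{conn.source}->{conn.target}"
        self.connections.append(conn)

    def add_drive(self, drive: PoissonDrive) -> None:
        if drive.target not in self.groups:
            raise ValueError(f"unknown group {drive.target!r}")
        self.drives.append(drive)


@dataclass
class SimulationResult:
    rasters: dict[str, SpikeRaster]
    weights: dict[str, SparseWeightMatrix]
    config: EngineConfig
    counters: Counters
    mean_rates: dict[str, float] = field(default_factory=dict)


def vectorized_state_update(group: NeuronGroup, dt: float, counters: Counters) -> np.ndarray:
    """Advance one neuron group by one step as whole-population array
    operations; scalar work is confined to spike handling.

    Exposed separately so tests can assert the vectorization contract:
    a silent (subthreshold) step performs zero per-spike events.
    """
    spiked = group.evolve(dt, "euler", 0.0)
    counters.vector_updates += 1
    counters.spike_events += int(spiked.size)
    return spiked


def run(network: Network, config: EngineConfig) -> SimulationResult:
    """Run the network for ``config.duration`` seconds of simulated time."""
    dt = config.dt
    dtype = config.dtype
    n_steps = config.n_steps
    counters = Counters()

    # --- initialization: one RNG stream per population -------------------
    for pop_index, group in enumerate(network.groups.values()):
        if isinstance(group, PoissonGroup):
            group.initialize(dt, (config.seed, pop_index))
        else:
            group.initialize(dtype, np.random.default_rng((config.seed, pop_index)))
    for k, drive in enumerate(network.drives):
        drive.input = PoissonCountInput(
            network.groups[drive.target].n, drive.rate, dt, (config.seed, 10_000 + k)
        )
    for conn in network.connections:
        if conn.delay_buffer is None:
            conn.delay_buffer = DelayBuffer(config.delay_steps)

    spike_times: dict[str, list] = {name: [] for name in network.groups}
    spike_ids: dict[str, list] = {name: [] for name in network.groups}

    neuron_groups = [g for g in network.groups.values() if isinstance(g, NeuronGroup)]
    report_every = max(1, int(round(1.0 / (dt * 1e-3))))  # one simulated second

    for step in range(n_steps):
        now = step * dt  # ms

        # (1) deliver delayed spikes, (2) plasticity on-pre
        delivered: dict[int, np.ndarray] = {}
        for ci, conn in enumerate(network.connections):
            arriving = conn.delay_buffer.deliver(step)
            delivered[ci] = arriving
            if arriving.size:
                target = network.groups[conn.target].state
                propagate(arriving, conn.matrix, getattr(target, conn.target_field))
                counters.spike_events += int(arriving.size)
        for ci, conn in enumerate(network.connections):
            if conn.plasticity is not None and delivered[ci].size:
                conn.plasticity.on_pre_delivered(delivered[ci], now)
        # external per-neuron Poisson drive enters with the delivered spikes
        for drive in network.drives:
            counts = drive.input.next_step_counts()
            target = network.groups[drive.target].state
            fieldvec = getattr(target, drive.target_field)
            fieldvec += (counts * drive.weight).astype(fieldvec.dtype)

        # (3) evolve neurons / draw Poisson spikes
        new_spikes: dict[str, np.ndarray] = {}
        for name, group in network.groups.items():
            if isinstance(group, PoissonGroup):
                new_spikes[name] = group.evolve()
            else:
                try:
                    new_spikes[name] = group.evolve(dt, config.integrator, config.rkf_tol)
                    counters.vector_updates += 1
                    counters.spike_events += int(new_spikes[name].size)
                except StateCorruptionError as exc:
                    raise StateCorruptionError(
                        f"{exc} (population {name!r}, step {step})"
                    ) from exc

        # (4) plasticity on-post, (5) trace updates
        for ci, conn in enumerate(network.connections):
            if conn.plasticity is None:
                continue
            conn.plasticity.on_post(new_spikes[conn.target], now)
        for ci, conn in enumerate(network.connections):
            if conn.plasticity is None:
                continue
            conn.plasticity.advance(delivered[ci], new_spikes[conn.target], now, dt)

        # (6) enqueue new spikes
        for conn in network.connections:
            spikes = new_spikes[conn.source]
            if spikes.size:
                conn.delay_buffer.enqueue(step, spikes)

        # (7) record
        t_now = step * dt * 1e-3
        for name, spikes in new_spikes.items():
            if spikes.size:
                spike_times[name].append(np.full(spikes.size, t_now))
                spike_ids[name].append(spikes)

        if config.progress and (step + 1) % report_every == 0:
            total = sum(sum(a.size for a in v) for v in spike_ids.values())
            print(
                f"[stdpsim] t = {(step + 1) * dt * 1e-3:.1f} s "
                f"({total} spikes so far)",
                flush=True,
            )

    rasters = {}
    mean_rates = {}
    for name, group in network.groups.items():
        if spike_ids[name]:
            times = np.concatenate(spike_times[name])
            ids = np.concatenate(spike_ids[name])
        else:
            times = np.empty(0)
            ids = np.empty(0, dtype=np.int64)
        rasters[name] = SpikeRaster(times, ids, n_units=group.n)
        mean_rates[name] = len(ids) / (group.n * config.duration) if group.n else 0.0
    weights = {conn.name: conn.matrix for conn in network.connections}
    return SimulationResult(rasters, weights, config, counters, mean_rates)
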