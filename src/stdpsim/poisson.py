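"""Fast generation of spikes from a homogeneous Poisson population.

The stride algorithm
--------------------
Consider a grid with N rows (one per Poisson unit) and one column per time
step.  Instead of drawing N inter-spike intervals per unit (which requires
book-keeping of N last spike times), each column is filled at the very
time step when its spikes are needed: starting from a carried-over
position, strides ``x ~ Exponential(mean 1/q)`` in cell units are drawn,
where ``q = rate * dt`` is the per-cell spike probability.  Every landing
position below N emits one spike at unit ``floor(position)``; a stride
crossing N is continued in the next time step by storing the overflow in
``carry``.  Every random number therefore yields exactly one spike.

The algorithm is valid for ``q < 1`` (at most one spike per unit per
step).  It is statistically equivalent to independent Bernoulli(q) draws
per grid cell up to O(q) corrections; :func:`bernoulli_grid_raster`
implements that brute-force scheme as an independent oracle.

A second input style, :class:`PoissonCountInput`, mirrors the classic
``poisson_generator`` of event-based simulators: each target neuron
receives an independent Poisson-distributed number of input events per
step.  Unlike the stride population it has no identity per input unit and
permits ``rate*dt >= 1``; it is used for the strong per-neuron external
drive of the balanced random (Brunel-type) network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import SpikeRaster

__all__ = ["PoissonPopulation", "PoissonCountInput", "bernoulli_grid_raster"]


@dataclass
class PoissonPopulation:
    """Homogeneous population of Poisson units using the stride algorithm.

    Parameters
    ----------
    n_units
        Population size N (>= 1).
    rate
        Per-unit firing rate in Hz (>= 0).
    dt
        Time step in ms.
    rng_seed
        Seed of the dedicated generator stream (int or sequence of ints).
    """

    n_units: int
    rate: float
    dt: float = 0.1
    rng_seed: int | tuple = 1
    carry: float = field(init=False)
    rng: np.random.Generator = field(init=False, repr=False)
    # counters for the one-spike-per-random-number invariant
    draws_consumed: int = field(init=False, default=0)
    spikes_emitted: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.q >= 1.0:
            raise ValueError(
                f"rate*dt = {self.q:.3g} >= 1: multiple spikes per unit per step "
                "are outside the validity of the stride algorithm"
            )
        self.rng = np.random.default_rng(self.rng_seed)
        # position of the first pending landing on the grid
        if self.q > 0:
            self.carry = self._draw_one()
        else:
            self.carry = np.inf

    @property
    def q(self) -> float:
        """Per-cell spike probability q = rate * dt (dt in seconds)."""
        return self.rate * self.dt * 1e-3

    def _draw_one(self) -> float:
        self.draws_consumed += 1
        return float(self.rng.exponential(1.0 / self.q))

    def next_step_spikes(self) -> np.ndarray:
        """Unit indices spiking in the next time step (ascending order)."""
        if self.q == 0.0:
            return np.empty(0, dtype=np.int64)
        out = []
        pos = self.carry
        n = self.n_units
        while pos < n:
            out.append(int(pos))
            self.spikes_emitted += 1
            pos += self._draw_one()
        self.carry = pos - n
        return np.asarray(out, dtype=np.int64)

    def generate_raster(self, duration: float) -> SpikeRaster:
        """Spike raster over ``duration`` seconds, timestamped on the dt grid.

        Vectorized equivalent of concatenating :meth:`next_step_spikes`
        over ``duration/dt`` steps: landing positions live on a virtual
        tape of ``n_steps * n_units`` cells traversed column by column, so
        a single cumulative sum of exponential strides reproduces the
        per-step carry semantics exactly (same generator stream, same
        spikes).
        """
        if duration <= 0:
            raise ValueError("duration must be > 0")
        n_steps = int(round(duration / (self.dt * 1e-3)))
        if self.q == 0.0 or n_steps == 0:
            return SpikeRaster(n_units=self.n_units)
        tape_len = float(n_steps) * self.n_units
        # landing positions: the pending carry, then cumulative strides
        chunks = [np.array([self.carry])]
        last = self.carry
        while last < tape_len:
            size = max(64, int((tape_len - last) * self.q * 1.05) + 32)
            landings = last + np.cumsum(self.rng.exponential(1.0 / self.q, size))
            cross = int(np.searchsorted(landings, tape_len))
            if cross < size:  # first landing beyond the tape: pending carry
                self.draws_consumed += cross + 1
                chunks.append(landings[: cross + 1])
                last = float(landings[cross])
            else:
                self.draws_consumed += size
                chunks.append(landings)
                last = float(landings[-1])
        all_landings = np.concatenate(chunks)
        inside = all_landings[all_landings < tape_len]
        self.carry = last - tape_len
        self.spikes_emitted += inside.size
        cells = np.floor(inside).astype(np.int64)
        times = (cells // self.n_units).astype(np.float64) * (self.dt * 1e-3)
        units = cells % self.n_units
        return SpikeRaster(times, units, n_units=self.n_units)


@dataclass
class PoissonCountInput:
    """Per-target independent Poisson event counts, one draw per step.

    Each of ``n_targets`` neurons receives ``Poisson(rate*dt)`` input
    events per time step, each contributing ``weight`` to the configured
    synaptic variable.  ``rate`` may exceed ``1/dt``.
    """

    n_targets: int
    rate: float
    dt: float = 0.1
    rng_seed: int | tuple = 1
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        self.rng = np.random.default_rng(self.rng_seed)
        self._lam = self.rate * self.dt * 1e-3

    def next_step_counts(self) -> np.ndarray:
        if self._lam == 0.0:
            return np.zeros(self.n_targets, dtype=np.int64)
        return self.rng.poisson(self._lam, size=self.n_targets)


def bernoulli_grid_raster(
    n_units: int, rate: float, dt: float, duration: float, seed: int | tuple = 1
) -> SpikeRaster:
    """Brute-force oracle: independent Bernoulli(q) per grid cell.

    Statistically indistinguishable from the stride generator at small q;
    used as the independent reference in tests.
    """
    q = rate * dt * 1e-3
    if q >= 1.0:
        raise ValueError("rate*dt must be < 1")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / (dt * 1e-3)))
    times_list = []
    ids_list = []
    for step in range(n_steps):
        hits = np.flatnonzero(rng.random(n_units) < q)
        if hits.size:
            ids_list.append(hits)
            times_list.append(np.full(hits.size, step * dt * 1e-3))
    if not ids_list:
        return SpikeRaster(n_units=n_units)
    return SpikeRaster(
        np.concatenate(times_list), np.concatenate(ids_list), n_units=n_units
    )
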