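"""Trace-based spike-timing-dependent plasticity.

Formalism
---------
Weight changes are driven by synaptic traces: exponentially decaying
low-pass filters of the pre- and postsynaptic spike trains,

    dz/dt = -z/tau + S(t),

so that an exponential-window STDP rule becomes event-based: on arrival of
a presynaptic spike at the synapse the postsynaptic trace ``z-`` is read
out and depression is applied; on a postsynaptic spike the presynaptic
trace ``z+`` is read out and potentiation is applied.  Non-Hebbian
per-spike terms ``a_pre``/``a_post`` are applied at the same events.

Timing conventions (shared by all rules and the brute-force oracle):

* All pre times are *arrival* times at the synapse.  With axonal delay
  semantics (the default), arrival = firing time + delay, and a
  postsynaptic spike in the same step as a presynaptic firing reaches the
  synapse first.
* Pairs interact all-to-all through the traces (no nearest-neighbor
  truncation).
* Exact zero-lag pairs (post spike in the very step a pre spike arrives)
  contribute nothing: each update only sees spikes from strictly earlier
  steps, because trace increments are applied at the end of a step.

Weight dependence follows the power-law family: the potentiation term is
scaled by ``(1 - w/w_max)**mu`` and the depression term by
``alpha * (w/w_max)**mu``; ``mu=0`` is the additive rule (with asymmetry
``alpha``) and ``mu=1`` the multiplicative rule.  Weights are clipped to
``[w_min, w_max]`` after every update.

Two update policies are provided: the default immediate policy applies
every update at the triggering event, which requires presynaptic traces
for all source neurons to be advanced continuously; the retrospective
policy (NEST-style) defers post-triggered updates and replays them in a
batch at the next presynaptic arrival from a bounded per-neuron spike
history, which also allows a dendritic interpretation of the delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import SparseWeightMatrix, multi_row_indices

__all__ = [
    "TraceState",
    "PairSTDPParams",
    "TripletSTDPParams",
    "WeightDependence",
    "PairSTDP",
    "TripletSTDP",
    "RetrospectivePairSTDP",
    "pairwise_oracle",
]


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------


class TraceState:
    """Exponentially decaying trace of a population's spike train.

    ``continuous`` mode is advanced every step by multiplication with
    ``exp(-dt/tau)``; ``event_based`` mode stores the last update time per
    unit and decays lazily using the exact closed-form solution.  Both
    modes agree at spike/read times to floating-point accuracy.
    Times are in ms.
    """

    def __init__(self, n: int, tau: float, mode: str = "continuous", dtype=np.float64):
        if tau <= 0:
            raise ValueError("tau must be > 0")
        if mode not in ("continuous", "event_based"):
            raise ValueError(f"unknown trace mode {mode!r}")
        self.n = int(n)
        self.tau = float(tau)
        self.mode = mode
        self.z = np.zeros(n, dtype=dtype)
        self.last_update = np.zeros(n, dtype=np.float64) if mode == "event_based" else None

    def decay_step(self, dt: float) -> "TraceState":
        """Continuous-mode decay: z <- z * exp(-dt/tau)."""
        if self.mode != "continuous":
            raise ValueError("decay_step applies to continuous traces only")
        self.z *= self.z.dtype.type(np.exp(-dt / self.tau))
        return self

    def on_spike(self, units, now: float = 0.0) -> "TraceState":
        """Register spikes of ``units`` at time ``now`` (ms).

        Event mode decays the affected units to ``now`` first; duplicated
        units within one call increment multiple times with zero-lag decay.
        """
        units = np.atleast_1d(np.asarray(units, dtype=np.int64))
        if units.size == 0:
            return self
        if self.mode == "event_based":
            uniq = np.unique(units)
            elapsed = now - self.last_update[uniq]
            if np.any(elapsed < 0):
                raise ValueError("spike time earlier than last trace update")
            self.z[uniq] *= np.exp(-elapsed / self.tau).astype(self.z.dtype)
            self.last_update[uniq] = now
        np.add.at(self.z, units, self.z.dtype.type(1.0))
        return self

    def get(self, units=None, now: float | None = None) -> np.ndarray:
        """Trace values (event mode: decayed to ``now`` without mutation)."""
        if units is None:
            units = np.arange(self.n)
        units = np.asarray(units, dtype=np.int64)
        vals = self.z[units]
        if self.mode == "event_based":
            if now is None:
                raise ValueError("event-based traces require a read time")
            elapsed = now - self.last_update[units]
            if np.any(elapsed < 0):
                raise ValueError("trace read earlier than last update")
            vals = vals * np.exp(-elapsed / self.tau).astype(vals.dtype)
        return vals


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightDependence:
    """Power-law interpolation between additive (mu=0) and multiplicative
    (mu=1) STDP; ``alpha`` scales depression relative to potentiation."""

    mu: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")

    def potentiation_factor(self, w: np.ndarray, w_max: float) -> np.ndarray:
        if self.mu == 0.0:
            return np.ones_like(w)
        base = np.clip(1.0 - w / w_max, 0.0, None)
        return base**self.mu

    def depression_factor(self, w: np.ndarray, w_max: float) -> np.ndarray:
        if self.mu == 0.0:
            return np.full_like(w, self.alpha)
        base = np.clip(w / w_max, 0.0, None)
        return self.alpha * base**self.mu


@dataclass(frozen=True)
class PairSTDPParams:
    """Exponential-window pair STDP: W(t) = a_plus*exp(-t/tau_plus) for
    t > 0 (pre-before-post) and -a_minus*exp(t/tau_minus) for t < 0."""

    a_plus: float = 1.0
    a_minus: float = 1.0
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    a_pre: float = 0.0
    a_post: float = 0.0
    w_min: float = 0.0
    w_max: float = np.inf
    learning_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be > 0")
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")


@dataclass(frozen=True)
class TripletSTDPParams:
    """Minimal all-to-all triplet rule (visual-cortex parameter set of the
    Pfister-Gerstner model as defaults; amplitudes are absolute weight
    changes per event, scaled by ``learning_rate``)."""

    a2_plus: float = 0.0
    a2_minus: float = 7.0e-3
    a3_plus: float = 6.2e-3
    a3_minus: float = 0.0
    tau_plus: float = 16.8
    tau_minus: float = 33.7
    tau_x: float = 101.0
    tau_y: float = 114.0
    w_min: float = 0.0
    w_max: float = np.inf
    learning_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_plus", "tau_minus", "tau_x", "tau_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# Immediate (Auryn-style) rules
# ---------------------------------------------------------------------------


class PairSTDP:
    """Pair STDP with immediate event-driven updates on one weight matrix.

    Presynaptic traces (indexed by source neuron) and postsynaptic traces
    are advanced once per step by the engine via :meth:`advance`; weight
    updates happen on presynaptic spike *arrival* (depression, reading the
    post trace) and on postsynaptic firing (potentiation, reading the pre
    trace through the backward view).
    """

    def __init__(
        self,
        m: SparseWeightMatrix,
        params: PairSTDPParams,
        weight_dependence: WeightDependence | None = None,
        trace_mode: str = "continuous",
        dtype=np.float64,
    ) -> None:
        self.m = m
        self.p = params
        self.wd = weight_dependence
        if (
            weight_dependence is not None
            and weight_dependence.mu > 0
            and not np.isfinite(params.w_max)
        ):
            raise ValueError("weight-dependent STDP with mu > 0 requires finite w_max")
        self.pre_trace = TraceState(m.n_pre, params.tau_plus, trace_mode, dtype)
        self.post_trace = TraceState(m.n_post, params.tau_minus, trace_mode, dtype)

    def on_pre_delivered(self, rows: np.ndarray, now: float) -> None:
        """Depression (and a_pre) when delayed presynaptic spikes arrive."""
        p = self.p
        if p.learning_rate == 0.0 or len(rows) == 0:
            return
        syn = multi_row_indices(self.m.fwd_ptr, rows)
        if syn.size == 0:
            return
        w = self.m.weights[syn]
        z = self.post_trace.get(self.m.targets[syn], now)
        dep = p.a_minus * z
        if self.wd is not None:
            dep = dep * self.wd.depression_factor(w.astype(np.float64), p.w_max)
        dw = p.learning_rate * (-dep + p.a_pre)
        self.m.weights[syn] = np.clip(w + dw.astype(w.dtype), p.w_min, p.w_max)

    def on_post(self, post_ids: np.ndarray, now: float) -> None:
        """Potentiation (and a_post) at postsynaptic firing times."""
        p = self.p
        if p.learning_rate == 0.0 or len(post_ids) == 0:
            return
        idx = multi_row_indices(self.m.bwd_ptr, post_ids)
        if idx.size == 0:
            return
        syn = self.m._bwd_syn[idx]
        sources = self.m._bwd_sources[idx]
        w = self.m.weights[syn]
        z = self.pre_trace.get(sources, now)
        pot = p.a_plus * z
        if self.wd is not None:
            pot = pot * self.wd.potentiation_factor(w.astype(np.float64), p.w_max)
        dw = p.learning_rate * (pot + p.a_post)
        self.m.weights[syn] = np.clip(w + dw.astype(w.dtype), p.w_min, p.w_max)

    def advance(
        self, delivered_rows: np.ndarray, new_post_ids: np.ndarray, now: float, dt: float
    ) -> None:
        """End-of-step trace update: register spikes, then decay by dt."""
        if self.pre_trace.mode == "continuous":
            self.pre_trace.on_spike(delivered_rows)
            self.pre_trace.decay_step(dt)
            self.post_trace.on_spike(new_post_ids)
            self.post_trace.decay_step(dt)
        else:
            self.pre_trace.on_spike(delivered_rows, now)
            self.post_trace.on_spike(new_post_ids, now)


class TripletSTDP:
    """Minimal all-to-all triplet STDP.

    On presynaptic arrival:  w -= lr * z-_post * (a2_minus + a3_minus * zx_pre)
    On postsynaptic firing:  w += lr * z+_pre  * (a2_plus  + a3_plus  * zy_post)

    where zx/zy are the slow traces read *before* their increment for the
    current spike.  With a3 = 0 the rule reduces exactly to pair STDP.
    """

    def __init__(
        self,
        m: SparseWeightMatrix,
        params: TripletSTDPParams,
        trace_mode: str = "continuous",
        dtype=np.float64,
    ) -> None:
        self.m = m
        self.p = params
        self.pre_fast = TraceState(m.n_pre, params.tau_plus, trace_mode, dtype)
        self.pre_slow = TraceState(m.n_pre, params.tau_x, trace_mode, dtype)
        self.post_fast = TraceState(m.n_post, params.tau_minus, trace_mode, dtype)
        self.post_slow = TraceState(m.n_post, params.tau_y, trace_mode, dtype)

    def on_pre_delivered(self, rows: np.ndarray, now: float) -> None:
        p = self.p
        if p.learning_rate == 0.0 or len(rows) == 0:
            return
        rows = np.asarray(rows, dtype=np.int64)
        syn = multi_row_indices(self.m.fwd_ptr, rows)
        if syn.size == 0:
            return
        w = self.m.weights[syn]
        zminus = self.post_fast.get(self.m.targets[syn], now)
        amp = p.a2_minus
        if p.a3_minus != 0.0:
            lens = self.m.fwd_ptr[rows + 1] - self.m.fwd_ptr[rows]
            # zero-length rows repeat zero times, matching multi_row_indices
            zx = np.repeat(self.pre_slow.get(rows, now), lens)
            amp = amp + p.a3_minus * zx
        dw = -p.learning_rate * zminus * amp
        self.m.weights[syn] = np.clip(w + dw.astype(w.dtype), p.w_min, p.w_max)

    def on_post(self, post_ids: np.ndarray, now: float) -> None:
        p = self.p
        if p.learning_rate == 0.0 or len(post_ids) == 0:
            return
        post_ids = np.asarray(post_ids, dtype=np.int64)
        idx = multi_row_indices(self.m.bwd_ptr, post_ids)
        if idx.size == 0:
            return
        syn = self.m._bwd_syn[idx]
        sources = self.m._bwd_sources[idx]
        w = self.m.weights[syn]
        zplus = self.pre_fast.get(sources, now)
        lens = self.m.bwd_ptr[post_ids + 1] - self.m.bwd_ptr[post_ids]
        zy = np.repeat(self.post_slow.get(post_ids, now), lens)
        dw = p.learning_rate * zplus * (p.a2_plus + p.a3_plus * zy)
        self.m.weights[syn] = np.clip(w + dw.astype(w.dtype), p.w_min, p.w_max)

    def advance(
        self, delivered_rows: np.ndarray, new_post_ids: np.ndarray, now: float, dt: float
    ) -> None:
        if self.pre_fast.mode == "continuous":
            for tr, units in (
                (self.pre_fast, delivered_rows),
                (self.pre_slow, delivered_rows),
                (self.post_fast, new_post_ids),
                (self.post_slow, new_post_ids),
            ):
                tr.on_spike(units)
                tr.decay_step(dt)
        else:
            for tr, units in (
                (self.pre_fast, delivered_rows),
                (self.pre_slow, delivered_rows),
                (self.post_fast, new_post_ids),
                (self.post_slow, new_post_ids),
            ):
                tr.on_spike(units, now)


# ---------------------------------------------------------------------------
# Brute-force pairwise oracle
# ---------------------------------------------------------------------------


def pairwise_oracle(
    pre_spikes, post_spikes, p: PairSTDPParams, weight_dependence=None
) -> float:
    """Total unclipped weight change of the pair rule by brute force.

    ``pre_spikes`` are synapse-local (arrival) times in ms.  Sums
    W(t_post - t_pre) over all pairs (zero-lag pairs contribute nothing)
    plus the non-Hebbian per-spike terms, all scaled by the learning rate.
    Valid in the additive regime (no clipping, no weight dependence).
    """
    if weight_dependence is not None:
        raise ValueError("the pairwise oracle is defined for the additive regime")
    pre = np.asarray(pre_spikes, dtype=np.float64)
    post = np.asarray(post_spikes, dtype=np.float64)
    total = p.a_pre * pre.size + p.a_post * post.size
    if pre.size and post.size:
        lag = np.subtract.outer(post, pre)  # t_post - t_pre_arrival
        total += p.a_plus * np.sum(np.exp(-lag[lag > 0] / p.tau_plus))
        total -= p.a_minus * np.sum(np.exp(lag[lag < 0] / p.tau_minus))
    return float(p.learning_rate * total)


# ---------------------------------------------------------------------------
# Retrospective (NEST-style) batched policy
# ---------------------------------------------------------------------------


class RetrospectivePairSTDP:
    """Pair STDP with batched retrospective updates at presynaptic arrival.

    Each postsynaptic neuron keeps a bounded history of recent firing
    times.  No weight is touched at postsynaptic spikes; when a
    presynaptic spike arrives, all deferred post-triggered potentiation
    updates since the previous arrival are replayed in time order (with
    presynaptic trace values reconstructed on the fly) and the depression
    update for the current arrival is applied last.  Under axonal delay
    semantics this reproduces the immediate policy exactly; setting
    ``dendritic=True`` instead interprets the transmission delay as
    dendritic (post spikes reach the synapse ``delay`` late, pre spikes
    ``delay`` early), which flips the sign class of close pairs.
    """

    def __init__(
        self,
        m: SparseWeightMatrix,
        params: PairSTDPParams,
        weight_dependence: WeightDependence | None = None,
        delay: float = 0.0,
        dendritic: bool = False,
        history_size: int = 1024,
    ) -> None:
        self.m = m
        self.p = params
        self.wd = weight_dependence
        self.delay = float(delay)
        self.dendritic = bool(dendritic)
        self.history_size = int(history_size)
        # effective post-spike time shift relative to pre-arrival times
        self._post_shift = 2.0 * self.delay if dendritic else 0.0
        self.history: list[list[float]] = [[] for _ in range(m.n_post)]
        self._evict_watermark = np.full(m.n_post, -np.inf)
        # compressed depression trace: value z_base at time t_base per post
        self._z_base = np.zeros(m.n_post)
        self._t_base = np.zeros(m.n_post)
        # per-presynaptic-row event trace with strict (pre-increment) reads
        self._z_pre = np.zeros(m.n_pre)
        self._z_pre_before = np.zeros(m.n_pre)
        self._t_last_arr = np.full(m.n_pre, -np.inf)

    # -- bookkeeping ----------------------------------------------------
    def record_post(self, post_ids: np.ndarray, now: float) -> None:
        """Store post firing times (called by the engine each step)."""
        t_eff = now + self._post_shift
        for i in np.asarray(post_ids, dtype=np.int64):
            h = self.history[int(i)]
            h.append(t_eff)
            if len(h) > self.history_size:
                old = h.pop(0)
                # fold evicted spike into the compressed depression trace
                zb, tb = self._z_base[i], self._t_base[i]
                self._z_base[i] = zb * np.exp(-(old - tb) / self.p.tau_minus) + 1.0
                self._t_base[i] = old
                self._evict_watermark[i] = old

    def _pre_trace_at(self, row: int, t: float) -> float:
        """Presynaptic trace from arrivals strictly before t."""
        t_last = self._t_last_arr[row]
        if t_last == -np.inf:
            return 0.0
        if t > t_last:
            return self._z_pre[row] * np.exp(-(t - t_last) / self.p.tau_plus)
        if t == t_last:
            return self._z_pre_before[row]
        raise ValueError("retrospective replay moved backwards in time")

    def _post_trace_at(self, i: int, t: float) -> float:
        """Depression trace of post neuron i at time t (spikes <= t)."""
        z = self._z_base[i] * np.exp(-(t - self._t_base[i]) / self.p.tau_minus)
        for u in self.history[i]:
            if u <= t:
                z += np.exp(-(t - u) / self.p.tau_minus)
        return z

    # -- the batched update ----------------------------------------------
    def on_pre_delivered(self, rows: np.ndarray, now: float) -> None:
        p = self.p
        for row in np.asarray(rows, dtype=np.int64):
            row = int(row)
            last_arr = self._t_last_arr[row]
            syn_ids = self.m.row_syn_ids(row)
            targets, _ = self.m.row(row)
            for syn, i in zip(syn_ids, targets):
                i = int(i)
                if last_arr < self._evict_watermark[i]:
                    raise RuntimeError(
                        "post spike history overflow: increase history_size"
                    )
                # replay deferred potentiation for posts in [last_arr, now)
                for u in self.history[i]:
                    if last_arr <= u < now:
                        w = float(self.m.weights[syn])
                        pot = p.a_plus * self._pre_trace_at(row, u)
                        if self.wd is not None:
                            pot *= float(
                                self.wd.potentiation_factor(np.float64(w), p.w_max)
                            )
                        w += p.learning_rate * (pot + p.a_post)
                        self.m.weights[syn] = np.clip(w, p.w_min, p.w_max)
                # depression for the current arrival
                w = float(self.m.weights[syn])
                dep = p.a_minus * self._post_trace_at(i, now)
                if self.wd is not None:
                    dep *= float(self.wd.depression_factor(np.float64(w), p.w_max))
                w += p.learning_rate * (-dep + p.a_pre)
                self.m.weights[syn] = np.clip(w, p.w_min, p.w_max)
            # advance the per-row pre trace (strict read support)
            if self._t_last_arr[row] == -np.inf:
                decayed = 0.0
            else:
                decayed = self._z_pre[row] * np.exp(
                    -(now - self._t_last_arr[row]) / p.tau_plus
                )
            self._z_pre_before[row] = decayed
            self._z_pre[row] = decayed + 1.0
            self._t_last_arr[row] = now

    def on_post(self, post_ids: np.ndarray, now: float) -> None:
        """No immediate work: post spikes are recorded by the engine."""

    def advance(self, delivered_rows, new_post_ids, now: float, dt: float) -> None:
        self.record_post(np.asarray(new_post_ids), now)

    def flush(self, now: float) -> None:
        """Apply all still-deferred potentiation updates (end of a run)."""
        p = self.p
        for row in range(self.m.n_pre):
            last_arr = self._t_last_arr[row]
            syn_ids = self.m.row_syn_ids(row)
            targets, _ = self.m.row(row)
            for syn, i in zip(syn_ids, targets):
                i = int(i)
                for u in self.history[i]:
                    if last_arr <= u <= now:
                        w = float(self.m.weights[syn])
                        pot = p.a_plus * self._pre_trace_at(row, u)
                        if self.wd is not None:
                            pot *= float(
                                self.wd.potentiation_factor(np.float64(w), p.w_max)
                            )
                        w += p.learning_rate * (pot + p.a_post)
                        self.m.weights[syn] = np.clip(w, p.w_min, p.w_max)
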