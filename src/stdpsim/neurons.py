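"""Leaky integrate-and-fire dynamics.

Two synapse models are supported:

* conductance-based (COBA): synaptic input enters as conductances that
  drive the membrane toward reversal potentials ``e_exc`` / ``e_inh``;
* current-based (CUBA): synaptic input enters directly as currents.

Both are advanced with the forward Euler method at a fixed step ``dt``,
which is the production integrator.  A vectorized embedded
Runge-Kutta-Fehlberg 4(5) step with adaptive sub-stepping is provided as a
high-order reference for precision studies.

Units and conventions
---------------------
Voltages are in mV and time constants in ms.  Conductances are expressed
in units of the leak conductance, so the subthreshold COBA equation reads

    tau_m * dv/dt = (v_rest - v) + g_exc*(e_exc - v) + g_inh*(e_inh - v) + i_bias

and the CUBA equation

    tau_m * dv/dt = (v_rest - v) + g_exc - g_inh + i_bias

where ``i_bias`` is the bias current times the membrane resistance (mV);
e.g. 200 pA through a 10 nS leak is ``i_bias = 20``.  In CUBA mode
``g_exc``/``g_inh`` hold positive current magnitudes (mV units) and decay
with ``tau_exc``/``tau_inh`` exactly like conductances.

Synaptic variables decay by the exact factor ``exp(-dt/tau)`` rather than
an Euler step: this is unconditionally stable and matches the update rule
used for plasticity traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LIFParams",
    "NeuronGroupState",
    "StateCorruptionError",
    "StepSizeUnderflowError",
    "evolve_coba_euler",
    "evolve_cuba_euler",
    "reference_step",
    "refractory_steps",
    "lif_firing_period",
]

#: Canonical conductance-based parameter set of the Vogels-Abbott style
#: balanced network (PyNN VAbenchmark lineage). All values overridable.
VA_COBA_DEFAULTS = dict(
    tau_mem=20.0,
    v_rest=-60.0,
    v_thr=-50.0,
    v_reset=-60.0,
    t_refractory=5.0,
    e_exc=0.0,
    e_inh=-80.0,
    tau_exc=5.0,
    tau_inh=10.0,
    i_bias=0.0,
)


class StateCorruptionError(RuntimeError):
    """Raised when a state vector contains NaN or Inf."""


class StepSizeUnderflowError(RuntimeError):
    """Raised when the adaptive reference integrator cannot meet tolerance."""


@dataclass(frozen=True)
class LIFParams:
    """Parameters of a leaky integrate-and-fire neuron group.

    All time constants in ms, potentials in mV, ``i_bias`` in mV
    (current times membrane resistance).
    """

    tau_mem: float = 20.0
    v_rest: float = -60.0
    v_thr: float = -50.0
    v_reset: float = -60.0
    t_refractory: float = 5.0
    e_exc: float = 0.0
    e_inh: float = -80.0
    tau_exc: float = 5.0
    tau_inh: float = 10.0
    i_bias: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_mem", "tau_exc", "tau_inh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.v_reset > self.v_thr:
            raise ValueError("v_reset must not exceed v_thr")
        if self.t_refractory < 0:
            raise ValueError("t_refractory must be >= 0")

    def with_overrides(self, **kwargs) -> "LIFParams":
        return replace(self, **kwargs)


def refractory_steps(params: LIFParams, dt: float) -> int:
    """Refractory duration as an integer number of steps, round(t_ref/dt)."""
    return int(round(params.t_refractory / dt))


@dataclass
class NeuronGroupState:
    """Per-neuron state vectors of one group.

    ``spiked`` holds the indices of neurons that crossed threshold in the
    most recent step.  ``refrac_count`` counts remaining refractory steps.
    """

    v: np.ndarray
    g_exc: np.ndarray
    g_inh: np.ndarray
    refrac_count: np.ndarray
    spiked: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @classmethod
    def zeros(cls, n: int, params: LIFParams, dtype=np.float32) -> "NeuronGroupState":
        return cls(
            v=np.full(n, params.v_rest, dtype=dtype),
            g_exc=np.zeros(n, dtype=dtype),
            g_inh=np.zeros(n, dtype=dtype),
            refrac_count=np.zeros(n, dtype=np.int64),
        )

    @property
    def n(self) -> int:
        return self.v.size

    def check_finite(self) -> None:
        for name in ("v", "g_exc", "g_inh"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise StateCorruptionError(f"non-finite values in state vector {name}")


def _threshold_reset(
    state: NeuronGroupState,
    params: LIFParams,
    ref_steps: int,
    entry_above: np.ndarray | None = None,
) -> None:
    """Apply threshold test (>=, tie fires), reset and refractory entry.

    A membrane at or above threshold fires whether it reached threshold
    before or after this step's integration (``entry_above`` marks neurons
    already at threshold on entry, so a leak pull-back within the step
    cannot mask the crossing).  Refractory neurons are clamped to v_reset
    and never appear in ``spiked``.  This is spike handling: the only
    place where work is proportional to the number of spiking neurons.
    """
    refractory = state.refrac_count > 0
    # clamp + count down for neurons still refractory at the start of the step
    state.v[refractory] = params.v_reset
    state.refrac_count[refractory] -= 1
    spiked_mask = (state.v >= params.v_thr) & ~refractory
    if entry_above is not None:
        spiked_mask |= entry_above & ~refractory
    spiked = np.flatnonzero(spiked_mask)
    if spiked.size:
        state.v[spiked] = params.v_reset
        state.refrac_count[spiked] = ref_steps
    state.spiked = spiked


def _decay_synapses(state: NeuronGroupState, params: LIFParams, dt: float) -> None:
    state.g_exc *= state.g_exc.dtype.type(np.exp(-dt / params.tau_exc))
    state.g_inh *= state.g_inh.dtype.type(np.exp(-dt / params.tau_inh))


def evolve_coba_euler(
    state: NeuronGroupState, params: LIFParams, dt: float
) -> NeuronGroupState:
    """One forward-Euler step of the conductance-based LIF group (in place).

    Order within the step: integrate v with the current conductances,
    exponentially decay the conductances, then threshold/reset.
    Refractory neurons do not integrate (their v stays clamped at reset).
    """
    state.check_finite()
    v = state.v
    entry_above = v >= params.v_thr
    scale = v.dtype.type(dt / params.tau_mem)
    dv = (
        (params.v_rest - v)
        + state.g_exc * (params.e_exc - v)
        + state.g_inh * (params.e_inh - v)
        + v.dtype.type(params.i_bias)
    )
    v += scale * dv
    _decay_synapses(state, params, dt)
    _threshold_reset(state, params, refractory_steps(params, dt), entry_above)
    return state


def evolve_cuba_euler(
    state: NeuronGroupState, params: LIFParams, dt: float
) -> NeuronGroupState:
    """One forward-Euler step of the current-based LIF group (in place).

    Identical to the COBA update except that synaptic input enters as
    currents without reversal-potential factors: excitatory input
    depolarizes by ``g_exc``, inhibitory input hyperpolarizes by ``g_inh``.
    """
    state.check_finite()
    v = state.v
    entry_above = v >= params.v_thr
    scale = v.dtype.type(dt / params.tau_mem)
    dv = (params.v_rest - v) + state.g_exc - state.g_inh + v.dtype.type(params.i_bias)
    v += scale * dv
    _decay_synapses(state, params, dt)
    _threshold_reset(state, params, refractory_steps(params, dt), entry_above)
    return state


# ---------------------------------------------------------------------------
# Reference integrator: embedded Runge-Kutta-Fehlberg 4(5)
# ---------------------------------------------------------------------------

# Fehlberg tableau (classic RKF45 coefficients)
_A = [
    [],
    [1 / 4],
    [3 / 32, 9 / 32],
    [1932 / 2197, -7200 / 2197, 7296 / 2197],
    [439 / 216, -8, 3680 / 513, -845 / 4104],
    [-8 / 27, 2, -3544 / 2565, 1859 / 4104, -11 / 40],
]
_B5 = np.array([16 / 135, 0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55])
_B4 = np.array([25 / 216, 0, 1408 / 2565, 2197 / 4104, -1 / 5, 0])


def _subthreshold_rhs(y: np.ndarray, params: LIFParams, coba: bool) -> np.ndarray:
    """RHS of the coupled (v, g_exc, g_inh) subthreshold system.

    ``y`` has shape (3, n).  The same continuous-time equations that the
    Euler integrator approximates, including exponential synapse decay.
    """
    v, ge, gi = y
    if coba:
        dv = (
            (params.v_rest - v)
            + ge * (params.e_exc - v)
            + gi * (params.e_inh - v)
            + params.i_bias
        ) / params.tau_mem
    else:
        dv = ((params.v_rest - v) + ge - gi + params.i_bias) / params.tau_mem
    return np.stack([dv, -ge / params.tau_exc, -gi / params.tau_inh])


def reference_step(
    state: NeuronGroupState,
    params: LIFParams,
    dt: float,
    tol: float = 1e-8,
    coba: bool = True,
) -> NeuronGroupState:
    """Advance the subthreshold dynamics by ``dt`` with adaptive RKF45.

    Sub-steps inside ``dt`` until the local error estimate (max-norm over
    all neurons and state variables) is below ``tol``.  Threshold, reset
    and refractoriness are applied on the ``dt`` grid, exactly as in the
    Euler integrators, so spike semantics are directly comparable.
    """
    state.check_finite()
    entry_above = state.v >= params.v_thr
    y = np.stack(
        [
            state.v.astype(np.float64),
            state.g_exc.astype(np.float64),
            state.g_inh.astype(np.float64),
        ]
    )
    t = 0.0
    h = dt
    min_h = dt * 1e-12
    while t < dt - 1e-15 * dt:
        h = min(h, dt - t)
        k = []
        for stage in range(6):
            yi = y.copy()
            for j, a in enumerate(_A[stage]):
                yi += h * a * k[j]
            k.append(_subthreshold_rhs(yi, params, coba))
        y5 = y + h * sum(b * ki for b, ki in zip(_B5, k))
        y4 = y + h * sum(b * ki for b, ki in zip(_B4, k))
        err = np.abs(y5 - y4)
        max_err = float(err.max()) if err.size else 0.0
        if max_err <= tol or h <= min_h:
            if h <= min_h and max_err > tol:
                worst = int(np.unravel_index(np.argmax(err), err.shape)[1])
                raise StepSizeUnderflowError(
                    f"step size underflow at neuron {worst}: "
                    f"local error {max_err:.3e} > tol {tol:.3e}"
                )
            t += h
            y = y5
            if max_err > 0:
                h *= min(4.0, max(0.1, 0.84 * (tol / max_err) ** 0.25))
            else:
                h *= 4.0
        else:
            h *= max(0.1, 0.84 * (tol / max_err) ** 0.25)
    dtype = state.v.dtype
    state.v = y[0].astype(dtype)
    state.g_exc = y[1].astype(dtype)
    state.g_inh = y[2].astype(dtype)
    _threshold_reset(state, params, refractory_steps(params, dt), entry_above)
    return state


def lif_firing_period(params: LIFParams) -> float:
    """Closed-form firing period (ms) of a LIF driven by constant i_bias.

    Valid when ``v_rest + i_bias > v_thr``; the period is the refractory
    time plus the exponential charge time from reset to threshold.
    """
    v_inf = params.v_rest + params.i_bias
    if v_inf <= params.v_thr:
        raise ValueError("bias current is subthreshold; the neuron never fires")
    t_charge = params.tau_mem * np.log(
        (v_inf - params.v_reset) / (v_inf - params.v_thr)
    )
    return params.t_refractory + t_charge
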