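"""Builders for the three benchmark networks.

All three are balanced random networks of integrate-and-fire neurons in
the asynchronous-irregular regime:

* ``vogels_abbott`` — the classic conductance-based (COBA) benchmark,
  3200 excitatory + 800 inhibitory neurons, 2% random connectivity
  (about 320k synapses), static weights, 0.8 ms delay, and a constant
  200 pA excitatory bias (20 mV through the 10 nS leak) that prevents the
  self-sustained state from dying out.
* ``brunel`` — a 10,000-cell current-based (CUBA) balanced network
  (8000 E / 2000 I, connection probability 0.1, ~1e7 synapses) with
  strong per-neuron external Poisson drive, after the classic sparsely
  connected random network; the plastic variant attaches multiplicative
  weight-dependent STDP to the E-to-E synapses.
* ``zenke25k`` — a 25,000-cell COBA network (20,000 E / 5000 I,
  ~3.4e7 synapses of which the ~2e7 E-to-E are plastic under triplet
  STDP) operating at a mean population rate of about 3 Hz.

Parameter provenance: population sizes, synapse counts, delays and the
Brunel/VA parameter lineage are standard; where a published description
leaves constants unspecified (notably the 25k network, whose detailed
tables are not reproduced here), the builders pin a reconstruction that
reproduces the stated sizes and operating rate, and every constant can be
overridden through the spec/config.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .connectivity import random_sparse_connect
from .engine import (
    Connection,
    EngineConfig,
    Network,
    NeuronGroup,
    PoissonDrive,
    PoissonGroup,
)
from .neurons import LIFParams, VA_COBA_DEFAULTS
from .plasticity import (
    PairSTDP,
    PairSTDPParams,
    RetrospectivePairSTDP,
    TripletSTDP,
    TripletSTDPParams,
    WeightDependence,
)

__all__ = [
    "NetworkSpec",
    "build_vogels_abbott",
    "build_brunel",
    "build_zenke25k",
    "build_network",
    "cuba_psp_peak",
    "MODEL_BUILDERS",
]


@dataclass
class NetworkSpec:
    """Declarative description of a network; ``build_network`` realizes it.

    populations: list of dicts with keys
        name, n, kind ("lif_coba" | "lif_cuba" | "poisson"),
        params (LIFParams kwargs) or rate, v_init ((lo, hi) or None)
    connections: list of dicts with keys
        source, target, p, w_init, target_field, plasticity (None or dict)
    drives: list of dicts with keys target, rate, weight, target_field
    """

    populations: list = dataclass_field(default_factory=list)
    connections: list = dataclass_field(default_factory=list)
    drives: list = dataclass_field(default_factory=list)
    dt: float = 0.1
    delay: float = 0.8
    duration: float = 1.0
    name: str = "custom"

    def validate(self) -> None:
        names = [p["name"] for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for p in self.populations:
            if p["n"] <= 0:
                raise ValueError(f"population {p['name']} has non-positive size")
            if p["kind"] not in ("lif_coba", "lif_cuba", "poisson"):
                raise ValueError(f"unknown population kind {p['kind']!r}")
            if p["kind"] != "poisson":
                LIFParams(**p.get("params", {}))  # raises on invalid params
        for c in self.connections:
            if c["source"] not in names or c["target"] not in names:
                raise ValueError("connection references unknown population")
            if not 0 <= c["p"] <= 1:
                raise ValueError("connection probability out of [0, 1]")
        for d in self.drives:
            if d["target"] not in names:
                raise ValueError("drive references unknown population")

    def to_config(self) -> dict:
        """Fully resolved parameter tree for provenance dumps."""
        return {
            "name": self.name,
            "dt": self.dt,
            "delay": self.delay,
            "duration": self.duration,
            "populations": copy.deepcopy(self.populations),
            "connections": copy.deepcopy(self.connections),
            "drives": copy.deepcopy(self.drives),
        }


def _make_plasticity(matrix, cfg: dict | None, delay: float):
    if cfg is None:
        return None
    cfg = dict(cfg)
    kind = cfg.pop("kind")
    wd_cfg = cfg.pop("weight_dependence", None)
    wd = WeightDependence(**wd_cfg) if wd_cfg else None
    trace_mode = cfg.pop("trace_mode", "continuous")
    if kind == "pair":
        return PairSTDP(matrix, PairSTDPParams(**cfg), wd, trace_mode=trace_mode)
    if kind == "triplet":
        return TripletSTDP(matrix, TripletSTDPParams(**cfg), trace_mode=trace_mode)
    if kind == "retrospective_pair":
        dendritic = cfg.pop("dendritic", False)
        history_size = cfg.pop("history_size", 1024)
        return RetrospectivePairSTDP(
            matrix,
            PairSTDPParams(**cfg),
            wd,
            delay=delay,
            dendritic=dendritic,
            history_size=history_size,
        )
    raise ValueError(f"unknown plasticity kind {kind!r}")


def build_network(spec: NetworkSpec, seed: int = 1) -> Network:
    """Realize a NetworkSpec: sample connectivity and wire everything up."""
    spec.validate()
    net = Network()
    for p in spec.populations:
        if p["kind"] == "poisson":
            net.add_group(PoissonGroup(p["name"], p["n"], p["rate"]))
        else:
            net.add_group(
                NeuronGroup(
                    p["name"],
                    p["n"],
                    LIFParams(**p.get("params", {})),
                    model="coba" if p["kind"] == "lif_coba" else "cuba",
                    v_init=p.get("v_init"),
                )
            )
    for ci, c in enumerate(spec.connections):
        n_pre = net.groups[c["source"]].n
        n_post = net.groups[c["target"]].n
        m = random_sparse_connect(
            n_pre,
            n_post,
            c["p"],
            c["w_init"],
            seed=(seed, 100 + ci),
            same_population=c["source"] == c["target"],
        )
        net.add_connection(
            Connection(
                c["source"],
                c["target"],
                m,
                target_field=c.get("target_field", "g_exc"),
                plasticity=_make_plasticity(m, c.get("plasticity"), spec.delay),
            )
        )
    for d in spec.drives:
        net.add_drive(
            PoissonDrive(
                d["target"], d["rate"], d["weight"], d.get("target_field", "g_exc")
            )
        )
    return net


# ---------------------------------------------------------------------------
# Vogels-Abbott benchmark
# ---------------------------------------------------------------------------


def build_vogels_abbott(
    duration: float = 60.0,
    delay: float = 0.8,
    dt: float = 0.1,
    n_exc: int = 3200,
    n_inh: int = 800,
    p: float = 0.02,
    w_exc: float = 0.4,
    w_inh: float = 5.1,
    i_bias: float = 20.0,
) -> NetworkSpec:
    """Conductance-based balanced network, ~320k synapses at p = 0.02.

    Weights are in units of the leak conductance (4 nS and 51 nS on a
    10 nS leak); ``i_bias`` is the constant excitatory current times the
    membrane resistance (200 pA * 100 MOhm = 20 mV).
    """
    params = dict(VA_COBA_DEFAULTS, i_bias=i_bias)
    pops = [
        dict(name="exc", n=n_exc, kind="lif_coba", params=params, v_init=(-60.0, -50.0)),
        dict(name="inh", n=n_inh, kind="lif_coba", params=params, v_init=(-60.0, -50.0)),
    ]
    conns = [
        dict(source="exc", target="exc", p=p, w_init=w_exc, target_field="g_exc"),
        dict(source="exc", target="inh", p=p, w_init=w_exc, target_field="g_exc"),
        dict(source="inh", target="exc", p=p, w_init=w_inh, target_field="g_inh"),
        dict(source="inh", target="inh", p=p, w_init=w_inh, target_field="g_inh"),
    ]
    return NetworkSpec(
        populations=pops,
        connections=conns,
        dt=dt,
        delay=delay,
        duration=duration,
        name="vogels_abbott",
    )


# ---------------------------------------------------------------------------
# Brunel network
# ---------------------------------------------------------------------------


def cuba_psp_peak(tau_mem: float, tau_syn: float) -> float:
    """Peak of the membrane PSP for a unit jump of the synaptic current
    variable in the CUBA model (v' = (-v + g)/tau_m, g' = -g/tau_s)."""
    if tau_mem == tau_syn:
        # degenerate limit: v(t) = (t/tau) exp(-t/tau)
        return float(np.exp(-1.0))
    t_star = np.log(tau_mem / tau_syn) / (1.0 / tau_syn - 1.0 / tau_mem)
    return float(
        tau_syn
        / (tau_mem - tau_syn)
        * (np.exp(-t_star / tau_mem) - np.exp(-t_star / tau_syn))
    )


def build_brunel(
    plastic: bool = False,
    duration: float = 20.0,
    delay: float = 0.8,
    dt: float = 0.1,
    n_exc: int = 8000,
    n_inh: int = 2000,
    p: float = 0.1,
    j_psp: float = 0.1,
    g: float = 5.0,
    eta: float = 2.0,
    tau_mem: float = 20.0,
    tau_syn: float = 0.5,
    v_thr: float = 20.0,
    t_refractory: float = 2.0,
    learning_rate: float = 1e-2,
    stdp_tau: float = 20.0,
    stdp_alpha: float = 2.02,
    stdp_mu: float = 1.0,
    w_max_factor: float = 3.0,
) -> NetworkSpec:
    """Current-based 10,000-cell balanced random network (~1e7 synapses).

    The voltage scale is normalized: resting/reset potential 0 mV,
    threshold ``v_thr`` = 20 mV.  ``j_psp`` is the peak EPSP of a single
    synapse (mV); inhibitory synapses are ``g`` times stronger.  Each
    neuron receives independent external Poisson drive of rate
    ``eta * nu_thr * C_E`` where ``nu_thr = v_thr / (j_psp * C_E *
    tau_mem)`` is the rate at which the mean external input alone reaches
    threshold.  All weights start uniform.

    ``plastic=True`` attaches weight-dependent (multiplicative, mu = 1)
    STDP to the E-to-E synapses with amplitude ``learning_rate`` per
    spike pair; with ``learning_rate=0`` the plastic and static variants
    produce identical seeded rasters.
    """
    c_e = p * n_exc  # excitatory in-degree
    w_exc = j_psp / cuba_psp_peak(tau_mem, tau_syn)  # synaptic amplitude, model units
    w_inh = g * w_exc
    nu_thr = v_thr / (j_psp * c_e * tau_mem * 1e-3)  # Hz
    ext_rate = eta * nu_thr * c_e  # Hz per neuron, Poisson counts per step
    params = dict(
        tau_mem=tau_mem,
        v_rest=0.0,
        v_thr=v_thr,
        v_reset=0.0,
        t_refractory=t_refractory,
        tau_exc=tau_syn,
        tau_inh=tau_syn,
        i_bias=0.0,
    )
    w_max = w_max_factor * w_exc
    plasticity = None
    if plastic:
        plasticity = dict(
            kind="pair",
            a_plus=w_max,
            a_minus=w_max * stdp_alpha,
            tau_plus=stdp_tau,
            tau_minus=stdp_tau,
            w_min=0.0,
            w_max=w_max,
            learning_rate=learning_rate,
            weight_dependence=dict(mu=stdp_mu, alpha=1.0),
        )
    pops = [
        dict(name="exc", n=n_exc, kind="lif_cuba", params=params, v_init=(0.0, v_thr)),
        dict(name="inh", n=n_inh, kind="lif_cuba", params=params, v_init=(0.0, v_thr)),
    ]
    conns = [
        dict(
            source="exc",
            target="exc",
            p=p,
            w_init=w_exc,
            target_field="g_exc",
            plasticity=plasticity,
        ),
        dict(source="exc", target="inh", p=p, w_init=w_exc, target_field="g_exc"),
        dict(source="inh", target="exc", p=p, w_init=w_inh, target_field="g_inh"),
        dict(source="inh", target="inh", p=p, w_init=w_inh, target_field="g_inh"),
    ]
    drives = [
        dict(target="exc", rate=ext_rate, weight=w_exc, target_field="g_exc"),
        dict(target="inh", rate=ext_rate, weight=w_exc, target_field="g_exc"),
    ]
    return NetworkSpec(
        populations=pops,
        connections=conns,
        drives=drives,
        dt=dt,
        delay=delay,
        duration=duration,
        name="brunel_plastic" if plastic else "brunel",
    )


# ---------------------------------------------------------------------------
# 25k-cell network
# ---------------------------------------------------------------------------


def build_zenke25k(
    scale: float = 1.0,
    duration: float = 10.0,
    delay: float = 0.8,
    dt: float = 0.1,
    p_ee: float = 0.05,
    p_other: float = 0.0622,
    w_ee: float = 0.05,
    w_ei: float = 0.05,
    w_ie: float = 0.5,
    w_ii: float = 0.5,
    ext_n: int = 5000,
    ext_rate: float = 10.0,
    ext_p: float = 0.05,
    ext_w: float = 0.15,
    learning_rate: float = 0.05,
    triplet: dict | None = None,
) -> NetworkSpec:
    """COBA network with 20,000 E and 5000 I cells at ``scale=1``.

    E-to-E connectivity at p_ee = 0.05 carries triplet STDP (~2e7 plastic
    synapses); the remaining blocks share ``p_other`` tuned so the total
    synapse count is ~3.4e7.  External drive comes from a homogeneous
    Poisson population.  Weight and drive constants are a reconstruction
    pinned to the published operating point (mean population rate ~3 Hz);
    all are overridable.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    n_exc = int(round(20000 * scale))
    n_inh = int(round(5000 * scale))
    n_ext = int(round(ext_n * scale))
    params = dict(VA_COBA_DEFAULTS)
    triplet_cfg = dict(
        kind="triplet",
        learning_rate=learning_rate,
        w_min=0.0,
        w_max=5.0 * w_ee,
    )
    if triplet:
        triplet_cfg.update(triplet)
    pops = [
        dict(name="exc", n=n_exc, kind="lif_coba", params=params, v_init=(-60.0, -50.0)),
        dict(name="inh", n=n_inh, kind="lif_coba", params=params, v_init=(-60.0, -50.0)),
        dict(name="ext", n=n_ext, kind="poisson", rate=ext_rate),
    ]
    conns = [
        dict(
            source="exc",
            target="exc",
            p=p_ee,
            w_init=w_ee,
            target_field="g_exc",
            plasticity=triplet_cfg,
        ),
        dict(source="exc", target="inh", p=p_other, w_init=w_ei, target_field="g_exc"),
        dict(source="inh", target="exc", p=p_other, w_init=w_ie, target_field="g_inh"),
        dict(source="inh", target="inh", p=p_other, w_init=w_ii, target_field="g_inh"),
        dict(source="ext", target="exc", p=ext_p, w_init=ext_w, target_field="g_exc"),
        dict(source="ext", target="inh", p=ext_p, w_init=ext_w, target_field="g_exc"),
    ]
    return NetworkSpec(
        populations=pops,
        connections=conns,
        dt=dt,
        delay=delay,
        duration=duration,
        name="zenke25k",
    )


MODEL_BUILDERS = {
    "vogels_abbott": build_vogels_abbott,
    "brunel": lambda **kw: build_brunel(plastic=False, **kw),
    "brunel_plastic": lambda **kw: build_brunel(plastic=True, **kw),
    "zenke25k": build_zenke25k,
}
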