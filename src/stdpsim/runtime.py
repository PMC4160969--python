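"""Strong-scaling run-time model: evaluation and fitting.

The total run time of a fixed-size parallel simulation decomposes as
T = T_sim + T_sync, where the compute part scales as alpha/n with core
count n and the synchronization part depends on the collective
communication algorithm: recursive-doubling/Bruck-style exchanges cost
beta*ceil(log2 n) + gamma*(n-1)/n while a ring exchange costs
beta*(n-1) + gamma*(n-1)/n (latency coefficient beta, bandwidth
coefficient gamma).  Both variants are bounded below by the
communication terms, so run times cannot be scaled down indefinitely.

The model is linear in (alpha, beta, gamma), so the RMS fit on absolute
run times is a nonnegativity-constrained linear least-squares problem; a
log-space option is available for data spanning wide dynamic ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

__all__ = [
    "RuntimeModelParams",
    "model_eval",
    "fit_model",
    "plasticity_overhead",
]

_VARIANTS = ("log2", "ring")


@dataclass(frozen=True)
class RuntimeModelParams:
    """Positive coefficients of the run-time model.

    alpha: per-core work; beta: latency per communication round;
    gamma: bandwidth term; variant: communication algorithm family.
    """

    alpha: float
    beta: float
    gamma: float
    variant: str = "log2"

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("parameters must be nonnegative")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")


def _design(n: np.ndarray, variant: str) -> np.ndarray:
    n = np.asarray(n, dtype=np.float64)
    if variant == "log2":
        comm = np.ceil(np.log2(n))
    elif variant == "ring":
        comm = n - 1.0
    else:
        raise ValueError(f"variant must be one of {_VARIANTS}")
    return np.column_stack([1.0 / n, comm, (n - 1.0) / n])


def model_eval(n, p: RuntimeModelParams) -> np.ndarray | float:
    """Predicted run time T(n); n may be a scalar or an array of ints >= 1."""
    arr = np.atleast_1d(np.asarray(n))
    if np.any(arr < 1) or np.any(arr != np.floor(arr)):
        raise ValueError("core counts must be integers >= 1")
    t = _design(arr, p.variant) @ np.array([p.alpha, p.beta, p.gamma])
    return float(t[0]) if np.isscalar(n) or np.ndim(n) == 0 else t


def fit_model(
    n_list,
    t_list,
    variant: str = "log2",
    log_space: bool = False,
    fix: dict | None = None,
) -> tuple[RuntimeModelParams, float]:
    """Nonnegativity-constrained RMS fit of the run-time model.

    ``fix`` holds parameters to clamp (e.g. ``{"beta": b, "gamma": c}`` to
    re-fit only alpha, the single-parameter refit used when transferring a
    model between simulators).  Returns (params, RMS residual, in the data
    units; log-units when ``log_space``).
    """
    n = np.asarray(n_list, dtype=np.float64)
    t = np.asarray(t_list, dtype=np.float64)
    if n.size != t.size or n.size < 3:
        raise ValueError("need at least 3 (n, T) measurements")
    if np.unique(n).size < 2:
        raise ValueError("degenerate design: all core counts identical")
    fix = dict(fix or {})
    names = ["alpha", "beta", "gamma"]
    free = [i for i, name in enumerate(names) if name not in fix]
    if not free:
        raise ValueError("at least one parameter must be free")
    x_fixed = np.array([fix.get(name, 0.0) for name in names])
    design = _design(n, variant)

    if not log_space:
        # linear in the parameters: bounded linear least squares
        target = t - design[:, [i for i in range(3) if names[i] in fix]] @ np.array(
            [fix[name] for name in names if name in fix]
        )
        sub = design[:, free]
        res = scipy.optimize.lsq_linear(sub, target, bounds=(0.0, np.inf))
        x = x_fixed.copy()
        x[free] = res.x
        residual = float(np.sqrt(np.mean((design @ x - t) ** 2)))
    else:
        if np.any(t <= 0):
            raise ValueError("log-space fit requires positive run times")

        def cost(xfree):
            x = x_fixed.copy()
            x[free] = xfree
            pred = design @ x
            return np.log(np.maximum(pred, 1e-300)) - np.log(t)

        x0 = np.full(len(free), max(t.mean(), 1e-6))
        res = scipy.optimize.least_squares(cost, x0, bounds=(0.0, np.inf))
        x = x_fixed.copy()
        x[free] = res.x
        residual = float(np.sqrt(np.mean(cost(res.x) ** 2)))
    params = RuntimeModelParams(
        alpha=float(x[0]), beta=float(x[1]), gamma=float(x[2]), variant=variant
    )
    return params, residual


def plasticity_overhead(t_pl: float, t_np: float) -> float:
    """Relative run-time increase caused by plasticity:
    chi = (T_PL - T_NP) / T_NP."""
    if t_pl < 0 or t_np <= 0:
        raise ValueError("run times must be positive")
    return (t_pl - t_np) / t_np
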