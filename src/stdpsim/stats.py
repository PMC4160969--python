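"""Comparison machinery for spike rasters.

Simulations run with different integrators or floating-point precisions
diverge microscopically (small perturbations grow exponentially in
balanced networks), so runs are compared at the level of macroscopic
network statistics: per-neuron firing rates, the population-pooled
inter-spike-interval (ISI) distribution, and the per-neuron coefficient
of variation of the ISI (CV ISI).  Distributions are compared with the
two-sample Kolmogorov-Smirnov test on the raw (unbinned) data; histograms
are only used for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.stats

from .raster import SpikeRaster

__all__ = [
    "KSResult",
    "firing_rates",
    "isi_and_cv",
    "ks_two_sample",
    "repeated_ks",
    "report",
]


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov outcome."""

    d_stat: float
    p_value: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_stat <= 1.0:
            raise ValueError("D must lie in [0, 1]")


def firing_rates(
    r: SpikeRaster, t0: float, t1: float, n_units: int | None = None
) -> np.ndarray:
    """Per-unit firing rate (Hz) over the window [t0, t1); silent units
    report 0."""
    if n_units is None:
        n_units = r.n_units
    if n_units is None:
        raise ValueError("n_units must be given for rasters of unknown size")
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    w = r.window(t0, t1)
    counts = np.bincount(w.ids, minlength=n_units).astype(np.float64)
    return counts / (t1 - t0)


def isi_and_cv(r: SpikeRaster, min_spikes_for_cv: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Pooled ISIs (s) and the per-unit CV ISI vector.

    ISIs are within-unit successive differences, pooled over the whole
    population.  CV = std(ISI)/mean(ISI) per unit, computed only for units
    with at least ``min_spikes_for_cv`` spikes (>= 2 ISIs); other units
    are excluded from the CV vector.
    """
    isis = []
    cvs = []
    for _unit, times in r.spike_trains().items():
        if times.size >= 2:
            d = np.diff(times)
            isis.append(d)
            if times.size >= min_spikes_for_cv:
                mean = d.mean()
                cvs.append(d.std() / mean if mean > 0 else 0.0)
    pooled = np.concatenate(isis) if isis else np.empty(0)
    return pooled, np.asarray(cvs, dtype=np.float64)


def ks_two_sample(a, b) -> KSResult:
    """Two-sample K-S test: D = sup |ECDF_a - ECDF_b| with the asymptotic
    p-value (sample sizes here are typically in the thousands)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("K-S test requires non-empty samples")
    res = scipy.stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue), a.size, b.size)


def _window_sample(r: SpikeRaster, t0: float, t1: float, measure: str) -> np.ndarray:
    w = r.window(t0, t1)
    if measure == "isi":
        sample, _ = isi_and_cv(w)
    elif measure == "cv":
        _, sample = isi_and_cv(w)
    elif measure == "rate":
        sample = firing_rates(w, t0, t1)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return sample


def repeated_ks(
    raster_a: SpikeRaster,
    raster_b: SpikeRaster,
    n_pairs: int = 10,
    t0: float = 0.0,
    t1: float | None = None,
    measure: str = "isi",
) -> tuple[float, float, list[KSResult]]:
    """Mean +- SD of the K-S statistic D over pairs of independent samples.

    The span [t0, t1] is divided into ``n_pairs`` equal, disjoint windows;
    pair k compares the samples of window k from raster A and raster B.
    Returns (mean D, SD of D, individual results).
    """
    if t1 is None:
        t1 = min(
            raster_a.times[-1] if len(raster_a) else 0.0,
            raster_b.times[-1] if len(raster_b) else 0.0,
        )
    if t1 <= t0:
        raise ValueError("empty comparison span")
    edges = np.linspace(t0, t1, n_pairs + 1)
    results = []
    for k in range(n_pairs):
        sa = _window_sample(raster_a, edges[k], edges[k + 1], measure)
        sb = _window_sample(raster_b, edges[k], edges[k + 1], measure)
        results.append(ks_two_sample(sa, sb))
    ds = np.array([r.d_stat for r in results])
    return float(ds.mean()), float(ds.std()), results


def _histogram_table(sample: np.ndarray, bins) -> str:
    hist, edges = np.histogram(sample, bins=bins)
    lines = ["# left_edge\tright_edge\tcount"]
    for lo, hi, c in zip(edges[:-1], edges[1:], hist):
        lines.append(f"{lo:.6g}\t{hi:.6g}\t{c}")
    return "\n".join(lines) + "\n"


def report(
    rasters: dict[str, SpikeRaster],
    out_dir,
    t0: float = 0.0,
    t1: float | None = None,
    bins="fd",
) -> Path:
    """Write rate / ISI / CV-ISI histogram tables, distribution means and a
    pairwise K-S table for the given rasters.  Returns the summary path."""
    if not rasters:
        raise ValueError("report requires at least one raster")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples: dict[str, dict[str, np.ndarray]] = {}
    summary = []
    for name, r in rasters.items():
        end = t1 if t1 is not None else (r.times[-1] if len(r) else 1.0)
        rate = firing_rates(r, t0, end)
        isi, cv = isi_and_cv(r.window(t0, end))
        samples[name] = {"rate": rate, "isi": isi, "cv": cv}
        for measure, sample in samples[name].items():
            if sample.size:
                (out / f"{name}_{measure}_hist.tsv").write_text(
                    _histogram_table(sample, bins)
                )
        summary.append(
            f"{name}: mean rate {rate.mean():.4f} Hz, "
            f"mean ISI {isi.mean():.6f} s ({isi.size} ISIs), "
            f"mean CV ISI {cv.mean() if cv.size else float('nan'):.4f}"
        )
    names = list(rasters)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for measure in ("rate", "isi", "cv"):
                sa, sb = samples[a][measure], samples[b][measure]
                if sa.size and sb.size:
                    res = ks_two_sample(sa, sb)
                    summary.append(
                        f"KS {measure} {a} vs {b}: D={res.d_stat:.5f} "
                        f"p={res.p_value:.4g} (n={res.n1},{res.n2})"
                    )
    path = out / "summary.txt"
    path.write_text("\n".join(summary) + "\n")
    return path
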