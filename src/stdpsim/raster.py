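"""Spike rasters: ordered (time, neuron id) events.

The raster is the universal exchange format of this package: every
simulation returns one per population, the statistics module consumes
them, and they round-trip through plain-text files (see :mod:`stdpsim.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeRaster"]


@dataclass
class SpikeRaster:
    """Ordered spike events of one population.

    Parameters
    ----------
    times
        Spike times in seconds, non-decreasing.
    ids
        Neuron indices (0-based), same length as ``times``.
    n_units
        Population size; ids must lie in ``[0, n_units)``.  ``None`` means
        unknown (e.g. raster loaded from a bare text file).
    """

    times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    n_units: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must have the same length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be non-decreasing")
        if self.n_units is not None and self.ids.size:
            if self.ids.min() < 0 or self.ids.max() >= self.n_units:
                raise ValueError("neuron ids out of population bounds")

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeRaster):
            return NotImplemented
        return (
            len(self) == len(other)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.ids, other.ids)
        )

    def window(self, t0: float, t1: float) -> "SpikeRaster":
        """Return the sub-raster with times in ``[t0, t1)``."""
        lo = np.searchsorted(self.times, t0, side="left")
        hi = np.searchsorted(self.times, t1, side="left")
        return SpikeRaster(self.times[lo:hi].copy(), self.ids[lo:hi].copy(), self.n_units)

    def spike_trains(self) -> dict[int, np.ndarray]:
        """Per-unit spike time arrays (only units that fired appear)."""
        order = np.argsort(self.ids, kind="stable")
        ids = self.ids[order]
        times = self.times[order]
        trains: dict[int, np.ndarray] = {}
        if ids.size == 0:
            return trains
        boundaries = np.flatnonzero(np.diff(ids)) + 1
        for chunk_ids, chunk_t in zip(
            np.split(ids, boundaries), np.split(times, boundaries)
        ):
            trains[int(chunk_ids[0])] = chunk_t
        return trains

    @staticmethod
    def concatenate(parts: list["SpikeRaster"], n_units: int | None = None) -> "SpikeRaster":
        if not parts:
            return SpikeRaster(n_units=n_units)
        times = np.concatenate([p.times for p in parts])
        ids = np.concatenate([p.ids for p in parts])
        return SpikeRaster(times, ids, n_units)
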