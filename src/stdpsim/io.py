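"""Plain-text file formats and configuration handling.

Rasters are human-readable text files with one ``time_in_seconds
neuron_id`` pair per line, ascending in time, one file per population.
Times are written with 5 decimal places so the 0.1 ms grid is exactly
representable; ids are 0-based (converters for 1-based dialects are
provided).  Configurations are YAML key-value trees with optional
``include`` composition; every simulation dumps its fully resolved
parameter tree so a run is reproducible from the dump alone.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import yaml

from .raster import SpikeRaster

__all__ = [
    "RasterParseError",
    "ConfigError",
    "read_raster",
    "write_raster",
    "load_config",
    "dump_config",
    "require_keys",
]


class RasterParseError(ValueError):
    """Malformed raster file (reports the offending line number)."""


class ConfigError(KeyError):
    """Missing required configuration key."""


def _format_time(t: float) -> str:
    """Shortest decimal that round-trips the float exactly, zero-padded to
    at least 5 decimal places (0.1 ms grid)."""
    s = np.format_float_positional(t, unique=True, trim="0")
    head, _, frac = s.partition(".")
    if len(frac) < 5:
        frac = frac.ljust(5, "0")
    return f"{head}.{frac}"


def write_raster(r: SpikeRaster, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for t, i in zip(r.times, r.ids):
            fh.write(f"{_format_time(t)} {i}\n")
    return path


def read_raster(path, n_units: int | None = None, one_based: bool = False) -> SpikeRaster:
    """Parse a ``time neuron_id`` text raster (any simulator's output)."""
    times = []
    ids = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            try:
                if len(parts) != 2:
                    raise ValueError
                t = float(parts[0])
                i = int(parts[1])
            except ValueError:
                raise RasterParseError(
                    f"{path}: line {lineno}: expected 'time neuron_id', got {s!r}"
                ) from None
            times.append(t)
            ids.append(i)
    ids_arr = np.asarray(ids, dtype=np.int64)
    if one_based:
        ids_arr = ids_arr - 1
    return SpikeRaster(np.asarray(times), ids_arr, n_units=n_units)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path, overrides: dict | None = None) -> dict:
    """Load a YAML config; an ``include`` key pulls in a base file first
    (values in the including file win), and ``overrides`` win over both."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    include = data.pop("include", None)
    if include:
        base = load_config(path.parent / include)
        data = _deep_merge(base, data)
    if overrides:
        data = _deep_merge(data, overrides)
    return data


def dump_config(config: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False, default_flow_style=False)
    return path


def require_keys(config: dict, keys, known: set | None = None) -> None:
    """Raise on missing required keys; warn (not fail) on unknown ones."""
    for key in keys:
        if key not in config:
            raise ConfigError(f"missing required config key {key!r}")
    if known is not None:
        for key in config:
            if key not in known:
                warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
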