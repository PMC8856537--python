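"""Configuration, track/field file formats, converters and provenance.

Canonical formats (all plain text, SI units):

* tracks CSV: columns ``fish_id, t_s, x_m, y_m, z_m`` (one row per record;
  an optional ``group_size`` column is carried through);
* field CSV: columns ``x, y, z, u, v, w[, tke][, alpha]`` (see flowfield);
* run configuration: YAML/JSON with strict key validation;
* pattern sets and rankings: JSON.

A converter ingests minute-resolution observation workbooks (XLSX) in which
several position records can share the same test minute; such records are
distributed evenly over the seconds of their minute, mirroring how the
observational protocol post-processes manually noted events.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .behavior import ParameterSet, SimulationConfig, VERSIONS
from .flowfield import FlumeGeometry
from .patterns import Track


class ConfigError(ValueError):
    """A run configuration violates the schema."""


@dataclass
class RunConfig:
    """Fully validated run configuration."""

    geometry: FlumeGeometry
    field_synthetic: Optional[dict]      # {"setup": "jet"|"nojet", ...}
    field_file: Optional[str]
    column_map: Optional[dict]
    params: ParameterSet
    version: str = "walldist"
    dt: float = 0.5
    n_fish: int = 100
    seeds: tuple = (0,)
    out_dir: str = "."
    log_level: str = "INFO"


_TOP_KEYS = {"geometry", "field", "params", "version", "dt", "n_fish",
             "seeds", "out_dir", "log_level"}
_GEOM_KEYS = {f for f in FlumeGeometry.__dataclass_fields__}
_FIELD_KEYS = {"synthetic", "file", "column_map"}
_SYNTH_KEYS = {"setup", "Q", "resolution", "seed"}


def _reject_unknown(d: Mapping, allowed, where: str) -> None:
    unknown = sorted(set(d) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(unknown)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected with their names; defaults are applied for
    everything omitted (dt = 0.5 s, 100 fish, default parameter set and
    flume geometry). Referenced field files must exist at load time.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "configuration")

    geom_d = raw.get("geometry", {}) or {}
    _reject_unknown(geom_d, _GEOM_KEYS, "geometry")
    geometry = FlumeGeometry(**geom_d)

    field_d = raw.get("field", {"synthetic": {}}) or {}
    _reject_unknown(field_d, _FIELD_KEYS, "field")
    synth = field_d.get("synthetic")
    ffile = field_d.get("file")
    if synth is not None and ffile is not None:
        raise ConfigError("field: give either 'synthetic' or 'file', not both")
    if synth is not None:
        _reject_unknown(synth, _SYNTH_KEYS, "field.synthetic")
        if synth.get("setup", "nojet") not in ("jet", "nojet"):
            raise ConfigError("field.synthetic.setup must be 'jet' or 'nojet'")
    if ffile is not None and not Path(ffile).exists():
        raise ConfigError(f"field.file does not exist: {ffile}")

    params_d = raw.get("params", {}) or {}
    _reject_unknown(params_d, ParameterSet.names(), "params")
    try:
        params = ParameterSet(**params_d)
    except ValueError as e:
        raise ConfigError(str(e)) from e

    dt = float(raw.get("dt", 0.5))
    if dt <= 0:
        raise ConfigError("dt must be positive")
    n_fish = int(raw.get("n_fish", 100))
    if n_fish < 1:
        raise ConfigError("n_fish must be >= 1")
    version = raw.get("version", "walldist")
    if version not in VERSIONS:
        raise ConfigError(
            f"version must be one of {', '.join(VERSIONS)}; got '{version}'")
    seeds = raw.get("seeds", [0])
    if isinstance(seeds, int):
        seeds = [seeds]
    return RunConfig(geometry=geometry, field_synthetic=synth,
                     field_file=ffile, column_map=field_d.get("column_map"),
                     params=params, version=version, dt=dt, n_fish=n_fish,
                     seeds=tuple(int(s) for s in seeds),
                     out_dir=str(raw.get("out_dir", ".")),
                     log_level=str(raw.get("log_level", "INFO")))


# ---------------------------------------------------------------------------
# Track files
# ---------------------------------------------------------------------------

def write_tracks(tracks: Sequence[Track], path) -> None:
    """Write tracks as the canonical CSV dialect."""
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "fish_id": tr.fish_id, "t_s": tr.t,
            "x_m": tr.x, "y_m": tr.y, "z_m": tr.z,
        }))
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        pd.DataFrame(columns=["fish_id", "t_s", "x_m", "y_m", "z_m"]).to_csv(
            path, index=False)


def read_tracks(path, body_length: float = 0.27,
                source: str = "observed") -> list:
    """Read tracks from the canonical CSV dialect (round-trips
    :func:`write_tracks` to full float precision)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed track file {path}: {e}") from e
    required = {"fish_id", "t_s", "x_m", "y_m", "z_m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"track file {path} is missing column(s): {', '.join(sorted(missing))}")
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() & ~df[col].isna())
        if bad.size:
            raise ValueError(f"non-numeric value in column '{col}' at line "
                             f"{int(bad[0]) + 2} of {path}")
        df[col] = vals
    tracks = []
    for fid, g in df.groupby("fish_id", sort=True):
        g = g.sort_values("t_s")
        tracks.append(Track(fish_id=int(fid), t=g["t_s"].to_numpy(),
                            x=g["x_m"].to_numpy(), y=g["y_m"].to_numpy(),
                            z=g["z_m"].to_numpy(), body_length=body_length,
                            source=source))
    return tracks


def spread_minute_events(minutes: np.ndarray) -> np.ndarray:
    """Assign seconds to minute-resolution events: the k-th of m events
    sharing a minute is placed at minute*60 + k*60/m."""
    minutes = np.asarray(minutes)
    t = np.empty(minutes.size, dtype=float)
    for m in np.unique(minutes):
        idx = np.flatnonzero(minutes == m)
        t[idx] = m * 60.0 + np.arange(idx.size) * 60.0 / idx.size
    return t


DEFAULT_XLSX_MAP = {"sheet": 0, "fish_id": "fish_id", "minute": "minute",
                    "x": "x_m", "y": "y_m", "z": "z_m"}


def convert_xlsx_tracks(path, column_map: Optional[Mapping] = None,
                        body_length: float = 0.27) -> list:
    """Convert a minute-resolution observation workbook to tracks.

    ``column_map`` names the sheet and the columns holding fish id, test
    minute and coordinates; events within the same minute are spread evenly
    over its seconds.
    """
    cm = dict(DEFAULT_XLSX_MAP)
    cm.update(column_map or {})
    df = pd.read_excel(path, sheet_name=cm["sheet"])
    for key in ("fish_id", "minute", "x", "y", "z"):
        if cm[key] not in df.columns:
            raise ValueError(f"workbook {path} is missing column '{cm[key]}'")
    tracks = []
    for fid, g in df.groupby(cm["fish_id"], sort=True):
        g = g.sort_values(cm["minute"], kind="stable")
        t = spread_minute_events(g[cm["minute"]].to_numpy())
        tracks.append(Track(fish_id=int(fid), t=t,
                            x=g[cm["x"]].to_numpy(dtype=float),
                            y=g[cm["y"]].to_numpy(dtype=float),
                            z=g[cm["z"]].to_numpy(dtype=float),
                            body_length=body_length, source="observed"))
    return tracks


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def write_provenance(out_dir, seed, config: Optional[Mapping] = None) -> Path:
    """Log what produced a result: config hash, seed and library versions."""
    import trutta
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    rec = {
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "trutta_version": getattr(trutta, "__version__", "unknown"),
        "numpy_version": np.__version__,
    }
    out = Path(out_dir) / "provenance.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(rec, indent=2) + "\n")
    return out
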