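"""Shared I/O: tidy CSV time series, CSV event tables, YAML configs.

All table outputs carry a provenance header (package version, seed, config
hash) as ``#``-prefixed comment lines; re-running a command with identical
inputs and seed reproduces byte-identical files.  The canonical time-series
schema is long format with columns ``time_h, variable, compartment, value,
units``; event tables are one row per event with the channel columns
(aliases can be mapped to canonical names via a configuration dict).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .model import ModelError, ModelParams, ScenarioConfig, TimeSeries
from .synth import CHANNELS, EventTable

__all__ = [
    "config_hash",
    "write_timeseries",
    "read_timeseries",
    "write_events",
    "read_events",
    "params_to_yaml",
    "params_from_yaml",
    "scenario_to_yaml",
    "scenario_from_yaml",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header(seed=None, config=None, extra: dict | None = None) -> str:
    lines = [f"# mucodyn {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _write_csv(df: pd.DataFrame, path, seed=None, config=None,
               extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    path.write_text(_header(seed, config, extra) + buf.getvalue())


def write_timeseries(ts: TimeSeries, path, seed=None, config=None) -> None:
    """Write a :class:`TimeSeries` as tidy CSV with a provenance header."""
    extra = {}
    if ts.f_att:
        extra["f_att"] = json.dumps(ts.f_att, sort_keys=True)
    if ts.meta:
        extra["meta"] = json.dumps(ts.meta, sort_keys=True, default=str)
    _write_csv(ts.to_tidy(), path, seed=seed, config=config, extra=extra)


def _read_commented_csv(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            stripped = line.lstrip("# ").rstrip("\n")
            if ": " in stripped:
                k, v = stripped.split(": ", 1)
                meta[k] = v
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    return df, meta


def read_timeseries(path) -> TimeSeries:
    """Read a tidy CSV time series; validates the schema and value ranges."""
    df, meta = _read_commented_csv(path)
    required = {"time_h", "variable", "compartment", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ModelError(f"time series table lacks columns {sorted(missing)}")
    cells = df["variable"].str.startswith(("bt_", "ri_"))
    bad = df[cells & (df["value"] < 0)]
    if len(bad):
        raise ModelError(
            f"negative cell densities at rows {bad.index.tolist()[:5]}")
    f_att = json.loads(meta["f_att"]) if "f_att" in meta else {}
    ts_meta = json.loads(meta["meta"]) if "meta" in meta else {}
    return TimeSeries.from_tidy(df, f_att=f_att, meta=ts_meta)


def write_events(events: EventTable, path, seed=None, config=None) -> None:
    extra = {"sample_id": events.sample_id, "role": events.role,
             "dilution": events.dilution,
             "acquisition_volume_ul": events.acquisition_volume_ul}
    if events.species_hint:
        extra["species_hint"] = events.species_hint
    _write_csv(events.data, path, seed=seed, config=config, extra=extra)


def read_events(path, channel_map: dict | None = None) -> EventTable:
    """Read an event table from CSV.

    ``channel_map`` renames instrument-specific column aliases to the
    canonical channel names (FSC, SSC, FL_SG, FL_PI).
    """
    df, meta = _read_commented_csv(path)
    if channel_map:
        df = df.rename(columns=channel_map)
    present = [c for c in CHANNELS if c in df.columns]
    if len(present) < 2:
        raise ModelError(
            f"event table must contain at least two of {CHANNELS}; "
            f"found {present} (use channel_map to rename aliases)")
    return EventTable(
        data=df,
        sample_id=meta.get("sample_id", Path(path).stem),
        role=meta.get("role", "sample"),
        species_hint=meta.get("species_hint") or None,
        dilution=float(meta.get("dilution", 200.0)),
        acquisition_volume_ul=float(meta.get("acquisition_volume_ul", 10.0)),
    )


def params_to_yaml(params: ModelParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))


def params_from_yaml(path) -> ModelParams:
    d = yaml.safe_load(Path(path).read_text()) or {}
    return ModelParams.from_dict(d)


def scenario_to_yaml(scenario: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=True))


def scenario_from_yaml(path) -> ScenarioConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    return ScenarioConfig.from_dict(d)
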