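"""Waveform CSV + sidecar-JSON reader/writer.

A record is stored as ``<name>.csv`` with columns
``time,paw,flow,volume,pes,dppl,cvp`` and ``<name>.json`` holding units,
annotations, ground-truth parameters (if any) and the simulation seed.
Round-tripping write → read reproduces channels bit-exactly.

Declared units are honoured on read: a pressure channel declared in mmHg
is converted to cmH2O (×1.36).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CHANNELS, CMH2O_PER_MMHG, Annotation, SchemaError, WaveformRecord

__all__ = ["read_record", "write_record"]

DEFAULT_UNITS = {"time": "s", "paw": "cmH2O", "flow": "L/s", "volume": "mL",
                 "pes": "cmH2O", "dppl": "cmH2O", "cvp": "cmH2O"}

_PRESSURE = {"paw", "pes", "dppl", "cvp"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_record(record: WaveformRecord, path: str | Path) -> Path:
    """Write a record to ``path`` (.csv) plus its sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time": record.time})
    for name in CHANNELS:
        df[name] = record.channels[name]
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "units": DEFAULT_UNITS,
        "annotations": [
            {"label": a.label, "t_start": a.t_start, "t_end": a.t_end}
            for a in record.annotations
        ],
        "truth": record.truth,
        "meta": record.meta,
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_record(path: str | Path) -> WaveformRecord:
    """Read a waveform CSV (+ sidecar JSON if present) into a record.

    Raises :class:`SchemaError` naming the offending field on a missing
    channel, non-uniform time grid, or unsupported unit.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time" not in df.columns:
        raise SchemaError("missing column 'time'")
    for name in CHANNELS:
        if name not in df.columns:
            raise SchemaError(f"missing column {name!r}")

    units = dict(DEFAULT_UNITS)
    annotations: list[Annotation] = []
    truth = None
    meta: dict = {}
    sc = _sidecar(path)
    if sc.exists():
        side = json.loads(sc.read_text())
        units.update(side.get("units") or {})
        annotations = [Annotation(a["label"], a["t_start"], a["t_end"])
                       for a in side.get("annotations", [])]
        truth = side.get("truth")
        meta = side.get("meta") or {}

    channels = {}
    for name in CHANNELS:
        values = df[name].to_numpy(dtype=float)
        unit = units.get(name, DEFAULT_UNITS[name])
        if name in _PRESSURE:
            if unit == "mmHg":
                values = values * CMH2O_PER_MMHG
            elif unit != "cmH2O":
                raise SchemaError(f"channel {name!r}: unsupported unit {unit!r}")
        elif unit != DEFAULT_UNITS[name]:
            raise SchemaError(f"channel {name!r}: unsupported unit {unit!r}")
        channels[name] = values

    return WaveformRecord(time=df["time"].to_numpy(dtype=float),
                          channels=channels, annotations=annotations,
                          truth=truth, meta=meta)
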