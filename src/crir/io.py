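"""Trace and result file formats.

Traces are plain CSV (columns ``time_s``, ``voltage_v``; seconds and volts
referred to amplifier input) with a JSON metadata sidecar at
``<path>.meta.json`` carrying protocol, settings, recording config and
provenance (seed, schema version).  Curves, fits, recommendations and
diagnosis reports serialize to JSON via their ``to_dict`` methods.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .signal_chain import RecordedTrace

__all__ = ["FormatError", "write_trace", "read_trace", "write_json", "read_json"]

_REL_DT_TOL = 1e-6


class FormatError(ValueError):
    """Malformed trace file; carries the first offending data line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"{message} (line {line})")


def write_trace(path: Union[str, Path], trace: RecordedTrace) -> Path:
    """Write a trace as CSV plus a JSON metadata sidecar; returns the path."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "voltage_v": trace.v_filter}).to_csv(
        path, index=False, float_format="%.9g"
    )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(trace.meta, indent=2, sort_keys=True))
    return path


def read_trace(path: Union[str, Path]) -> RecordedTrace:
    """Read a CSV trace, validating uniform, strictly increasing sampling."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "voltage_v"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}", line=1)
    time = df["time_s"].to_numpy(dtype=float)
    v = df["voltage_v"].to_numpy(dtype=float)
    if len(time) < 2:
        raise FormatError("trace needs at least two samples", line=2)
    dt = np.diff(time)
    bad = np.nonzero(dt <= 0)[0]
    if len(bad):
        raise FormatError("time_s must be strictly increasing", line=int(bad[0]) + 3)
    off = np.nonzero(np.abs(dt - dt[0]) > _REL_DT_TOL * dt[0])[0]
    if len(off):
        raise FormatError("non-uniform sampling interval", line=int(off[0]) + 3)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return RecordedTrace(time=time, v_filter=v, meta=meta)


def write_json(path: Union[str, Path], obj: dict) -> Path:
    """Deterministic JSON output (sorted keys, fixed float repr)."""
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))
    return path


def read_json(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())
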