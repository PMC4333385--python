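"""CSV + JSON-sidecar persistence for transient traces.

A trace lives in ``<name>.csv`` with the two-column header ``time_s,signal``
(comma separator, '.' decimal, UTF-8), and a sidecar ``<name>.json``
carrying the observable id and the experiment metadata (concentrations,
condition, seed, noise model).  Round trips are lossless at full floating
precision (repr-level formatting).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .transients import TransientTrace

__all__ = ["read_trace", "write_trace", "TraceParseError", "sidecar_path"]


class TraceParseError(ValueError):
    """Malformed trace CSV; the message carries the offending line number."""


def sidecar_path(path: Path | str) -> Path:
    return Path(path).with_suffix(".json")


def write_trace(trace: TransientTrace, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["time_s,signal"]
    lines += [f"{float(t)!r},{float(s)!r}" for t, s in zip(trace.time, trace.signal)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    sidecar = {"observable": trace.observable, "meta": trace.meta}
    sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n",
                                  encoding="utf-8")
    return path


def read_trace(path: Path | str) -> TransientTrace:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines()]
    if not lines or lines[0].strip() != "time_s,signal":
        raise TraceParseError(f"{path}:1: expected header 'time_s,signal'")
    times, signals = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise TraceParseError(f"{path}:{lineno}: expected 2 comma-separated fields")
        try:
            times.append(float(parts[0]))
            signals.append(float(parts[1]))
        except ValueError as exc:
            raise TraceParseError(f"{path}:{lineno}: {exc}") from None
    side = sidecar_path(path)
    if side.exists():
        payload = json.loads(side.read_text(encoding="utf-8"))
        observable = payload.get("observable", "unknown")
        meta = payload.get("meta", {})
    else:
        warnings.warn(f"missing sidecar for {path}; observable set to 'unknown'",
                      stacklevel=2)
        observable, meta = "unknown", {}
    return TransientTrace(np.asarray(times), np.asarray(signals), observable, meta)
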