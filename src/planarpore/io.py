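"""Text-first readers and writers for traces, event tables and configs.

Traces are two-column (time_s, current_pA) tab-delimited text with a sidecar
``<path>.meta.json`` carrying sample rate, holding potential, solutions and
provenance. Event tables share one dialect between simulator ground truth
and idealizer output: a header line then (start_ms, duration_ms, level)
rows, so truth and estimate are directly comparable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from .records import IdealizedRecord, RawTrace, Segment

__all__ = [
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "meta_path",
]

_REQUIRED_META = ("sample_rate_hz", "holding_potential_mV")
_EVENT_HEADER = "start_ms\tduration_ms\tlevel"


def meta_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_trace(trace: RawTrace, path: str | Path) -> None:
    """Write a trace and its sidecar metadata; lossless round-trip."""
    path = Path(path)
    t = trace.times
    with path.open("w") as fh:
        fh.write("time_s\tcurrent_pA\n")
        for ti, xi in zip(t, trace.samples):
            fh.write(f"{ti:.17g}\t{xi:.17g}\n")
    meta = dict(trace.metadata)
    meta["sample_rate_hz"] = trace.sample_rate
    meta["holding_potential_mV"] = trace.holding_potential
    meta["n_samples"] = trace.n_samples
    meta_path(path).write_text(json.dumps(_jsonable(meta), indent=1))


def read_trace(path: str | Path) -> RawTrace:
    """Read a trace; validates metadata completeness and uniform sampling."""
    path = Path(path)
    mpath = meta_path(path)
    if not mpath.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {mpath}")
    meta = json.loads(mpath.read_text())
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise ValueError(f"metadata missing required keys: {missing}")
    times, samples = [], []
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("time_s"):
            raise ValueError(f"{path}:1: expected 'time_s\\tcurrent_pA' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                times.append(float(parts[0]))
                samples.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not samples:
        raise ValueError(f"{path}: no samples")
    fs = float(meta["sample_rate_hz"])
    t = np.asarray(times)
    expected = np.arange(len(t)) / fs
    if np.any(np.abs(t - expected) > 1e-9 * np.maximum(1.0, np.abs(expected))):
        raise ValueError(f"{path}: time column not uniform at {fs} Hz")
    extra = {
        k: v for k, v in meta.items()
        if k not in ("sample_rate_hz", "holding_potential_mV", "n_samples")
    }
    return RawTrace(
        samples=np.asarray(samples),
        sample_rate=fs,
        holding_potential=float(meta["holding_potential_mV"]),
        metadata=extra,
    )


def write_events(record: IdealizedRecord, path: str | Path) -> None:
    """Write an event (dwell) table: start_ms, duration_ms, level."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_EVENT_HEADER + "\n")
        for seg in record.segments:
            fh.write(f"{seg.start * 1e3:.17g}\t{seg.duration * 1e3:.17g}\t{seg.level}\n")


def read_events(path: str | Path, source: str = "truth") -> IdealizedRecord:
    """Read an event table back into an IdealizedRecord; validates contiguity."""
    path = Path(path)
    segments: list[Segment] = []
    with path.open() as fh:
        header = fh.readline().strip()
        if header.split() != _EVENT_HEADER.split():
            raise ValueError(f"{path}:1: expected header '{_EVENT_HEADER}'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected three columns")
            try:
                start_ms, dur_ms = float(parts[0]), float(parts[1])
                level = int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            segments.append(Segment(start_ms / 1e3, dur_ms / 1e3, level))
    if not segments:
        raise ValueError(f"{path}: empty event table")
    return IdealizedRecord(segments=segments, source=source)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
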