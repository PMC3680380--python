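"""Shared record containers for traces and idealized (piecewise-constant) records.

Conventions used package-wide: currents in pA, potentials in mV (cis minus
trans, trans grounded), conductances in pS, concentrations in mM. Durations
are seconds internally; the on-disk event-table dialect uses milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Segment", "RawTrace", "IdealizedRecord"]


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant stretch of a record: ``level`` channels open."""

    start: float  # s
    duration: float  # s
    level: int

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class RawTrace:
    """Uniformly sampled current record.

    samples : pA; holding_potential : mV; sample_rate : Hz.
    ``metadata`` carries provenance (solutions, ensemble truth, seed, ...).
    """

    samples: np.ndarray
    sample_rate: float
    holding_potential: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


class RecordValidationError(ValueError):
    pass


@dataclass
class IdealizedRecord:
    """Piecewise-constant occupancy-level record.

    Segments are contiguous, non-overlapping, cover [0, duration], and
    adjacent segments differ in level. ``source`` is one of
    {"hmm", "threshold", "truth"}.
    """

    segments: list[Segment]
    source: str = "truth"
    level_means: np.ndarray | None = None  # pA, fitted amplitudes if known
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise RecordValidationError("record has no segments")
        if self.source not in ("hmm", "threshold", "truth"):
            raise RecordValidationError(f"unknown source {self.source!r}")
        prev_end = 0.0
        prev_level = None
        for seg in self.segments:
            if seg.duration <= 0:
                raise RecordValidationError("segment with non-positive duration")
            if seg.level < 0 or seg.level != int(seg.level):
                raise RecordValidationError("levels must be non-negative integers")
            if abs(seg.start - prev_end) > 1e-9 * max(1.0, prev_end):
                raise RecordValidationError(
                    f"segments not contiguous at t={seg.start:.9g} s"
                )
            if prev_level is not None and seg.level == prev_level:
                raise RecordValidationError("adjacent segments share a level")
            prev_end = seg.end
            prev_level = seg.level

    @property
    def duration(self) -> float:
        return self.segments[-1].end

    @property
    def max_level(self) -> int:
        return max(s.level for s in self.segments)

    def durations_by_level(self) -> dict[int, float]:
        """Total time spent at each occupancy level, in seconds."""
        out: dict[int, float] = {}
        for seg in self.segments:
            out[seg.level] = out.get(seg.level, 0.0) + seg.duration
        return out

    def level_at_samples(self, sample_rate: float, n_samples: int) -> np.ndarray:
        """Occupancy level at each sample instant k/sample_rate."""
        starts = np.array([s.start for s in self.segments])
        levels = np.array([s.level for s in self.segments], dtype=int)
        t = np.arange(n_samples) / sample_rate
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(levels) - 1)
        return levels[idx]


def merge_segments(raw: list[tuple[float, float, int]]) -> list[Segment]:
    """Build a valid segment list, merging adjacent equal-level stretches."""
    merged: list[Segment] = []
    for start, dur, level in raw:
        if dur <= 0:
            continue
        if merged and merged[-1].level == level:
            last = merged[-1]
            merged[-1] = Segment(last.start, (start + dur) - last.start, level)
        else:
            merged.append(Segment(start, dur, level))
    return merged
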