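"""Synthetic multi-channel bilayer recording generator.

Simulates N independent, identical channels gating by a continuous-time
Markov scheme over states C (closed), O (open) and B (open-channel blocked),
with Eyring-like voltage-dependent rates k(V) = k0 * exp(V / v_e). The
ensemble's summed open-level sequence is rendered into a current trace:
unitary current i = g * (V - Erev), 4-pole low-pass filtering, then additive
Gaussian noise. The blocked state is electrically indistinguishable from
closed (full occlusion), so brief blocks appear as incompletely resolved
closures once filtered — the morphology that motivates the binomial
open-probability estimator downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import signal

from .records import IdealizedRecord, RawTrace, Segment, merge_segments

__all__ = [
    "Rate",
    "GatingScheme",
    "EnsembleConfig",
    "RecordingConfig",
    "Dwell",
    "EventSequence",
    "sample_ctmc",
    "aggregate",
    "render_trace",
    "simulate_experiment",
    "simulate_voltage_series",
    "lowpass_sos",
    "filter_delay_samples",
]

_STATES = ("C", "O", "B")
_OPEN_STATES = frozenset({"O"})


@dataclass(frozen=True)
class Rate:
    """Voltage-dependent rate constant k(V) = k0 * exp(V / v_e).

    k0 in s^-1 (for blocker entry pass k0 = k_on * [blocker] with k_on in
    s^-1 uM^-1); v_e is the e-fold voltage in mV, +/-inf for a
    voltage-independent rate.
    """

    k0: float
    v_e: float = math.inf

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise ValueError("rate constants must be non-negative")
        if self.v_e == 0:
            raise ValueError("v_e must be nonzero (use inf for V-independence)")

    def at(self, v_mv: float) -> float:
        if not math.isfinite(self.v_e):
            return self.k0
        return self.k0 * math.exp(v_mv / self.v_e)


@dataclass(frozen=True)
class GatingScheme:
    """Per-channel kinetic scheme over states from {C, O, B}.

    ``rates`` maps ordered state pairs to Rate objects. The blocked state B
    may only be entered from O (open-channel block).
    """

    states: tuple[str, ...]
    rates: dict[tuple[str, str], Rate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        unknown = set(self.states) - set(_STATES)
        if unknown:
            raise ValueError(f"unknown states {sorted(unknown)}; allowed: C, O, B")
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate states")
        for (a, b), rate in self.rates.items():
            if a not in self.states or b not in self.states or a == b:
                raise ValueError(f"invalid rate key {(a, b)!r}")
            if b == "B" and a != "O" and rate.k0 > 0:
                raise ValueError("blocked state B is reachable only from O")
        self._check_irreducible()

    def _check_irreducible(self) -> None:
        # states touched by any nonzero rate must form one strongly
        # connected component (otherwise some state is absorbing/unreachable)
        active = {s for (a, b), r in self.rates.items() if r.k0 > 0 for s in (a, b)}
        if len(active) < 2:
            return
        for start in active:
            seen = {start}
            stack = [start]
            while stack:
                s = stack.pop()
                for (a, b), r in self.rates.items():
                    if a == s and r.k0 > 0 and b in active and b not in seen:
                        seen.add(b)
                        stack.append(b)
            if seen != active:
                raise ValueError(
                    f"scheme not irreducible: {sorted(active - seen)} unreachable "
                    f"from {start}"
                )

    # -- convenience constructors -------------------------------------------
    @classmethod
    def two_state(
        cls,
        k_co: float,
        k_oc: float,
        v_e_co: float = math.inf,
        v_e_oc: float = math.inf,
    ) -> "GatingScheme":
        """C <-> O scheme; stationary Po = k_co / (k_co + k_oc) at fixed V."""
        return cls(
            states=("C", "O"),
            rates={("C", "O"): Rate(k_co, v_e_co), ("O", "C"): Rate(k_oc, v_e_oc)},
        )

    def with_block(
        self,
        k_on: float,
        blocker_conc: float,
        k_off: float,
        v_e_on: float = math.inf,
        v_e_off: float = math.inf,
    ) -> "GatingScheme":
        """Add open-channel block O <-> B; entry rate k_on*[blocker] (uM)."""
        if "B" in self.states:
            raise ValueError("scheme already has a blocked state")
        rates = dict(self.rates)
        rates[("O", "B")] = Rate(k_on * blocker_conc, v_e_on)
        rates[("B", "O")] = Rate(k_off, v_e_off)
        return GatingScheme(states=self.states + ("B",), rates=rates)

    # -- kinetics ------------------------------------------------------------
    def q_matrix(self, v_mv: float) -> np.ndarray:
        """Generator matrix at holding potential V (rows sum to zero)."""
        n = len(self.states)
        idx = {s: i for i, s in enumerate(self.states)}
        q = np.zeros((n, n))
        for (a, b), rate in self.rates.items():
            k = rate.at(v_mv)
            if not math.isfinite(k):
                raise ValueError(f"rate {a}->{b} not finite at {v_mv} mV")
            q[idx[a], idx[b]] = k
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary(self, v_mv: float) -> np.ndarray:
        """Stationary distribution of the chain at V."""
        q = self.q_matrix(v_mv)
        n = len(self.states)
        a = np.vstack([q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        total = pi.sum()
        if total <= 0:
            raise ValueError("stationary distribution undefined (all rates zero?)")
        return pi / total

    def open_probability(self, v_mv: float) -> float:
        """Stationary single-channel open probability at V."""
        pi = self.stationary(v_mv)
        return float(sum(p for s, p in zip(self.states, pi) if s in _OPEN_STATES))


@dataclass(frozen=True)
class EnsembleConfig:
    """N identical independent channels with unitary conductance g (pS)."""

    scheme: GatingScheme
    n_channels: int = 1
    conductance: float = 395.0  # pS
    reversal_potential: float = 0.0  # mV

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.conductance <= 0:
            raise ValueError("conductance must be positive")

    def unitary_current(self, v_mv: float) -> float:
        """i = g (V - Erev), in pA (pS * mV / 1000)."""
        return self.conductance * (v_mv - self.reversal_potential) / 1000.0


@dataclass(frozen=True)
class RecordingConfig:
    """Acquisition settings for rendering a trace."""

    holding_potential: float  # mV
    duration: float = 30.0  # s
    sample_rate: float = 10_000.0  # Hz
    filter_corner: float = 1_000.0  # Hz, 4-pole low-pass
    noise_sd: float = 1.0  # pA, post-filter

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate < 5 * self.filter_corner:
            raise ValueError("sample_rate must be at least 5x filter_corner")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class Dwell:
    state: str
    entry_time: float  # s
    duration: float  # s


@dataclass
class EventSequence:
    """Ground truth: per-channel dwell lists plus the aggregate level walk."""

    per_channel: list[list[Dwell]]
    aggregate: list[Segment]
    duration: float
    n_channels: int

    def to_record(self, **metadata: Any) -> IdealizedRecord:
        return IdealizedRecord(
            segments=list(self.aggregate), source="truth", metadata=metadata
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def sample_ctmc(
    scheme: GatingScheme,
    v_mv: float,
    duration: float,
    rng: np.random.Generator | int,
    start: str | None = None,
) -> list[Dwell]:
    """Exact-time Gillespie realization of one channel over [0, duration].

    The initial state is drawn from the stationary distribution at V unless
    ``start`` names a state. A state with no exit routes dwells to the end of
    the record (valid only with an explicit start).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = {s: i for i, s in enumerate(scheme.states)}
    q = scheme.q_matrix(v_mv)
    if start is None:
        pi = scheme.stationary(v_mv)
        state = int(rng.choice(len(scheme.states), p=pi))
    else:
        if start not in idx:
            raise ValueError(f"unknown start state {start!r}")
        state = idx[start]

    dwells: list[Dwell] = []
    t = 0.0
    while t < duration:
        out_rates = q[state].copy()
        out_rates[state] = 0.0
        total = out_rates.sum()
        if total <= 0.0:
            dwells.append(Dwell(scheme.states[state], t, duration - t))
            break
        dt = rng.exponential(1.0 / total)
        dwell = min(dt, duration - t)
        dwells.append(Dwell(scheme.states[state], t, dwell))
        if t + dt >= duration:
            break
        t += dt
        state = int(rng.choice(len(scheme.states), p=out_rates / total))
    return dwells


def aggregate(
    channels: Sequence[list[Dwell]], n_channels: int, duration: float | None = None
) -> list[Segment]:
    """Sum of per-channel open indicators as a piecewise-constant level walk.

    Merges all per-channel changepoints; the returned segment durations
    partition the record exactly.
    """
    if len(channels) != n_channels:
        raise ValueError("number of dwell lists must equal n_channels")
    if duration is None:
        duration = max(d[-1].entry_time + d[-1].duration for d in channels)
    events: list[tuple[float, int]] = []
    for dwells in channels:
        t_end = 0.0
        for dw in dwells:
            if abs(dw.entry_time - t_end) > 1e-9 * max(1.0, t_end):
                raise ValueError("per-channel dwells do not partition the record")
            t_end = dw.entry_time + dw.duration
            if dw.state in _OPEN_STATES:
                events.append((dw.entry_time, +1))
                events.append((min(t_end, duration), -1))
        if abs(t_end - duration) > 1e-9 * max(1.0, duration):
            raise ValueError("per-channel dwells do not span the full duration")
    events.sort()
    raw: list[tuple[float, float, int]] = []
    level = 0
    t_prev = 0.0
    for t, delta in events:
        if t > t_prev:
            raw.append((t_prev, t - t_prev, level))
            t_prev = t
        level += delta
    if duration > t_prev:
        raw.append((t_prev, duration - t_prev, level))
    segments = merge_segments(raw)
    if not segments:
        segments = [Segment(0.0, duration, 0)]
    if any(s.level < 0 or s.level > n_channels for s in segments):
        raise ValueError("aggregate level outside [0, n_channels]")
    return segments


def lowpass_sos(filter_corner: float, sample_rate: float) -> np.ndarray:
    """4-pole Bessel-type digital low-pass used for trace rendering."""
    return signal.bessel(4, filter_corner, fs=sample_rate, output="sos", norm="mag")


def filter_delay_samples(filter_corner: float, sample_rate: float) -> int:
    """Low-frequency group delay of the rendering filter, in whole samples.

    The causal 4-pole filter delays every event by this nearly constant lag;
    use it to align idealized records with simulator ground truth.
    """
    sos = lowpass_sos(filter_corner, sample_rate)
    b, a = signal.sos2tf(sos)
    _, gd = signal.group_delay((b, a), w=[1e-4], fs=sample_rate)
    return int(round(float(gd[0])))


def render_trace(
    seq: EventSequence,
    ens: EnsembleConfig,
    rec: RecordingConfig,
    rng: np.random.Generator | int | None = None,
    metadata: dict[str, Any] | None = None,
) -> RawTrace:
    """Render an EventSequence into a sampled, filtered, noisy current trace.

    The ideal level(t) * g * (V - Erev) waveform is sampled at
    ``rec.sample_rate``, passed through a causal 4-pole low-pass at
    ``rec.filter_corner``, then Gaussian noise of SD ``rec.noise_sd`` is
    added (so noise_sd is the observed baseline SD). Closures shorter than
    roughly 0.33/filter_corner are visibly attenuated, as in real bilayer
    recordings.
    """
    if rec.sample_rate < 2 * rec.filter_corner:
        raise ValueError("sample_rate below Nyquist for the filter corner")
    if seq.duration < rec.duration - 1e-9:
        raise ValueError("event sequence does not cover the recording duration")
    n = int(round(rec.duration * rec.sample_rate))
    record = IdealizedRecord(segments=list(seq.aggregate), source="truth")
    levels = record.level_at_samples(rec.sample_rate, n)
    i_unit = ens.unitary_current(rec.holding_potential)
    ideal = levels * i_unit
    sos = lowpass_sos(rec.filter_corner, rec.sample_rate)
    zi = signal.sosfilt_zi(sos) * ideal[0]
    filtered, _ = signal.sosfilt(sos, ideal, zi=zi)
    if rec.noise_sd > 0:
        rng = np.random.default_rng(rng)
        filtered = filtered + rng.normal(0.0, rec.noise_sd, n)
    meta = {
        "sample_rate_hz": rec.sample_rate,
        "holding_potential_mV": rec.holding_potential,
        "filter_corner_hz": rec.filter_corner,
        "noise_sd_pA": rec.noise_sd,
        "n_channels": ens.n_channels,
        "conductance_pS": ens.conductance,
        "reversal_potential_mV": ens.reversal_potential,
    }
    if metadata:
        meta.update(metadata)
    return RawTrace(
        samples=filtered,
        sample_rate=rec.sample_rate,
        holding_potential=rec.holding_potential,
        metadata=meta,
    )


def simulate_experiment(
    ens: EnsembleConfig,
    rec: RecordingConfig,
    seed: int | np.random.SeedSequence = 0,
    solutions: Any | None = None,
) -> tuple[RawTrace, EventSequence]:
    """One-call protocol runner: paired (observed trace, ground truth).

    Deterministic under a fixed seed: per-channel gating and recording noise
    draw from independent child streams of the seed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(ens.n_channels + 1)
    v = rec.holding_potential
    channels = [
        sample_ctmc(ens.scheme, v, rec.duration, np.random.default_rng(children[i]))
        for i in range(ens.n_channels)
    ]
    seq = EventSequence(
        per_channel=channels,
        aggregate=aggregate(channels, ens.n_channels, rec.duration),
        duration=rec.duration,
        n_channels=ens.n_channels,
    )
    meta: dict[str, Any] = {"seed": _seed_repr(ss)}
    if solutions is not None:
        meta["solutions"] = solutions
    trace = render_trace(
        seq, ens, rec, rng=np.random.default_rng(children[-1]), metadata=meta
    )
    return trace, seq


def simulate_voltage_series(
    ens: EnsembleConfig,
    base_rec: RecordingConfig,
    voltages: Sequence[float],
    seed: int | np.random.SeedSequence = 0,
    solutions: Any | None = None,
) -> dict[float, tuple[RawTrace, EventSequence]]:
    """Simulate one recording per holding potential (the i-V protocol)."""
    from dataclasses import replace

    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    out: dict[float, tuple[RawTrace, EventSequence]] = {}
    for child, v in zip(root.spawn(len(voltages)), voltages):
        rec = replace(base_rec, holding_potential=float(v))
        out[float(v)] = simulate_experiment(ens, rec, seed=child, solutions=solutions)
    return out


def _seed_repr(ss: np.random.SeedSequence) -> Any:
    ent = ss.entropy
    return int(ent) if isinstance(ent, int) and ent < 2**63 else str(ent)
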