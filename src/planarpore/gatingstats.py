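"""Open-probability statistics for multi-channel bilayer records.

With N independent, identical channels in a bilayer, the collective open
probability Po(N) — the fraction of time all N channels are simultaneously
open — relates to the single-channel open probability through the binomial
model, Po(N) = Po^N, so Po = Po(N)^(1/N). This module implements that
estimator, the conventional 50%-threshold occupancy-weighted comparator
Po = sum_k k T_k / (N T), N estimation from the maximum coincident open
level, dwell-time summaries, Po-voltage tables and blocker-effect
comparisons (Welch two-sample test).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import IdealizedRecord

__all__ = [
    "PoEstimate",
    "DwellTable",
    "BlockComparison",
    "estimate_n",
    "po_collective",
    "po_binomial",
    "po_threshold_method",
    "estimate_po",
    "dwell_times",
    "po_voltage_table",
    "compare_block",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PoEstimate:
    """Open-probability estimate from one record.

    po_collective is Po(N); po is the single-channel estimate. For the
    binomial method po = Po(N)^(1/N) >= Po(N).
    """

    po_collective: float
    n_channels: int
    po: float
    method: str  # "binomial" | "threshold"
    duration: float  # s
    voltage: float | None = None  # mV

    def __post_init__(self) -> None:
        for name in ("po_collective", "po"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.method not in ("binomial", "threshold"):
            raise ValueError("method must be 'binomial' or 'threshold'")


@dataclass
class DwellTable:
    """Per-level dwell durations (s), censored end segments excluded."""

    dwells: dict[int, list[float]]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "level": lvl,
                "n_dwells": len(d),
                "mean_s": float(np.mean(d)) if d else np.nan,
                "median_s": float(np.median(d)) if d else np.nan,
            }
            for lvl, d in sorted(self.dwells.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class BlockComparison:
    """Welch-test comparison of Po between control and blocker groups."""

    condition: tuple[float | None, float | None]  # (blocker uM, voltage mV)
    po_control: list[float]
    po_treated: list[float]
    statistic: float
    p_value: float
    df: float
    alpha: float
    significant: bool
    warning: str | None = None


# ---------------------------------------------------------------------------


def estimate_n(record: IdealizedRecord) -> int:
    """N = maximum number of coincidentally open channels in the record.

    This estimator can only undercount (a channel that never opens during
    the recording is invisible); it never exceeds the true channel count.
    """
    n = record.max_level
    if n < 1:
        raise ValueError("record never leaves level 0: no channel evidence")
    return n


def po_collective(record: IdealizedRecord, n: int) -> float:
    """Po(N): time spent at level n as a proportion of the record duration."""
    if n < 1:
        raise ValueError("n must be >= 1")
    durations = record.durations_by_level()
    if n > record.max_level:
        warnings.warn(
            f"record never reaches level {n} (max {record.max_level}); Po(N)=0",
            stacklevel=2,
        )
    return durations.get(n, 0.0) / record.duration


def po_binomial(po_collective: float, n: int) -> float:
    """Single-channel Po from the binomial model: Po = Po(N)^(1/N)."""
    if not 0.0 <= po_collective <= 1.0:
        raise ValueError("po_collective must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(po_collective ** (1.0 / n))


def po_threshold_method(record: IdealizedRecord, n: int) -> float:
    """Conventional occupancy-weighted open fraction: sum_k k T_k / (n T)."""
    if n < record.max_level:
        raise ValueError(
            f"n={n} below the maximum level {record.max_level} present in the record"
        )
    durations = record.durations_by_level()
    weighted = sum(k * t for k, t in durations.items())
    return weighted / (n * record.duration)


def estimate_po(
    record: IdealizedRecord,
    n: int | None = None,
    method: str = "binomial",
    voltage: float | None = None,
) -> PoEstimate:
    """Full Po estimate from a record; N from the record unless supplied.

    A user-supplied ``n`` larger than the observed maximum level overrides
    the (downward-biased) max-level estimate, with a logged warning.
    """
    n_hat = estimate_n(record)
    if n is None:
        n = n_hat
    elif n > n_hat:
        log.warning(
            "user n_channels=%d overrides observed maximum level %d", n, n_hat
        )
    elif n < n_hat:
        raise ValueError(f"n={n} below observed maximum open level {n_hat}")
    if method == "binomial":
        pon = po_collective(record, n)
        po = po_binomial(pon, n)
    elif method == "threshold":
        po = po_threshold_method(record, n)
        pon = po_collective(record, n)
    else:
        raise ValueError("method must be 'binomial' or 'threshold'")
    return PoEstimate(
        po_collective=pon,
        n_channels=n,
        po=po,
        method=method,
        duration=record.duration,
        voltage=voltage,
    )


def dwell_times(record: IdealizedRecord) -> DwellTable:
    """Per-level dwell durations; first and last segments are censored (their
    true lengths extend beyond the record) and excluded."""
    segs = record.segments
    interior = segs[1:-1] if len(segs) > 2 else []
    dwells: dict[int, list[float]] = {}
    for seg in interior:
        dwells.setdefault(seg.level, []).append(seg.duration)
    return DwellTable(dwells=dwells)


def po_voltage_table(
    records_by_voltage: Mapping[float, Sequence[IdealizedRecord]],
    n: int | None = None,
    method: str = "binomial",
) -> pd.DataFrame:
    """Mean +/- SD of Po across recordings at each holding potential.

    Inconsistent estimated N across recordings at one voltage is flagged in
    the ``flags`` column, not fatal. Empty voltage groups are omitted with a
    warning.
    """
    rows = []
    for v in sorted(records_by_voltage):
        records = records_by_voltage[v]
        if not records:
            warnings.warn(f"no recordings at {v} mV; omitted", stacklevel=2)
            continue
        estimates = [estimate_po(r, n=n, method=method, voltage=v) for r in records]
        ns = {e.n_channels for e in estimates}
        pos = [e.po for e in estimates]
        rows.append(
            {
                "voltage_mV": v,
                "po_mean": float(np.mean(pos)),
                "po_sd": float(np.std(pos, ddof=1)) if len(pos) > 1 else 0.0,
                "n_recordings": len(pos),
                "flags": "inconsistent_n" if len(ns) > 1 else "",
            }
        )
    return pd.DataFrame(rows)


def compare_block(
    control: Iterable[PoEstimate | float],
    treated: Iterable[PoEstimate | float],
    alpha: float = 0.005,
    blocker_conc: float | None = None,
    voltage: float | None = None,
) -> BlockComparison:
    """Welch unequal-variance two-sample test on Po between groups."""
    po_c = [e.po if isinstance(e, PoEstimate) else float(e) for e in control]
    po_t = [e.po if isinstance(e, PoEstimate) else float(e) for e in treated]
    if len(po_c) < 2 or len(po_t) < 2:
        raise ValueError("both groups need at least 2 estimates")
    warning = None
    if np.var(po_c) == 0.0 and np.var(po_t) == 0.0:
        identical = np.mean(po_c) == np.mean(po_t)
        warning = "zero-variance groups; exact-equality comparison"
        stat, p, df = (0.0 if identical else np.inf), (1.0 if identical else 0.0), np.nan
    else:
        res = stats.ttest_ind(po_c, po_t, equal_var=False)
        stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return BlockComparison(
        condition=(blocker_conc, voltage),
        po_control=po_c,
        po_treated=po_t,
        statistic=stat,
        p_value=p,
        df=df,
        alpha=alpha,
        significant=bool(p < alpha),
        warning=warning,
    )
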