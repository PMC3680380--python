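"""Current-voltage and conductance-concentration analyses.

Unitary-current extraction from fitted level amplitudes, slope-conductance
linear regression of the i-V relation (slope in pA/mV converted to pS), and
the single-site binding hyperbola g(a) = g_max * a / (K_a + a) describing
conductance saturation with permeant-ion activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .idealization import HmmFit
from .records import IdealizedRecord

__all__ = [
    "IVPoint",
    "ConductanceFit",
    "SaturationFit",
    "unitary_amplitudes",
    "fit_iv_linear",
    "fit_binding_hyperbola",
]


@dataclass(frozen=True)
class IVPoint:
    """One point of a unitary current-voltage relation."""

    voltage: float  # mV
    unitary_current: float  # pA
    sem: float = 0.0  # pA
    n_obs: int = 1

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")


@dataclass
class ConductanceFit:
    """Linear i-V regression: slope conductance (pS) and reversal potential."""

    conductance: float  # pS
    erev: float  # mV (zero-current crossing)
    conductance_se: float
    erev_se: float
    residuals: np.ndarray
    n_points: int


@dataclass
class SaturationFit:
    """Single-site binding hyperbola fit g(a) = g_max a / (K_a + a)."""

    g_max: float  # pS
    k_a: float  # mM
    g_max_se: float
    k_a_se: float
    converged: bool
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, a) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        return self.g_max * a / (self.k_a + a)


# ---------------------------------------------------------------------------


def unitary_amplitudes(record: IdealizedRecord, fit: HmmFit) -> tuple[float, float]:
    """Unitary current (pA) from the fitted level amplitudes.

    Regresses the fitted level means on the level index over the levels the
    record actually visits — the generalization of the mean adjacent-level
    spacing that stays exact for equidistant levels. Returns (i_unit, se).
    """
    visited = sorted(record.durations_by_level())
    means = fit.emission.level_means
    visited = [k for k in visited if k < means.size]
    if len(visited) < 2:
        raise ValueError("record visits fewer than two levels; no unitary amplitude")
    k = np.array(visited, dtype=float)
    y = means[visited]
    coef, cov = np.polyfit(k, y, 1, cov=True) if len(visited) > 2 else (
        np.polyfit(k, y, 1),
        None,
    )
    i_unit = float(coef[0])
    se = float(np.sqrt(cov[0, 0])) if cov is not None else 0.0
    return i_unit, se


def fit_iv_linear(points: list[IVPoint], weighted: bool = False) -> ConductanceFit:
    """Ordinary least squares of unitary current on voltage.

    Slope (pA/mV) is converted to pS (x1000); the zero-current crossing is
    reported as the reversal potential. ``weighted`` applies 1/SEM^2 weights
    (points with zero SEM are given the smallest nonzero SEM).
    """
    if len(points) < 2:
        raise ValueError("need at least two i-V points")
    v = np.array([p.voltage for p in points], dtype=float)
    i = np.array([p.unitary_current for p in points], dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("need at least two distinct voltages")
    w = None
    if weighted:
        sems = np.array([p.sem for p in points], dtype=float)
        nonzero = sems[sems > 0]
        floor = nonzero.min() if nonzero.size else 1.0
        w = 1.0 / np.maximum(sems, floor) ** 2
    if len(points) > 2:
        coef, cov = np.polyfit(v, i, 1, w=np.sqrt(w) if w is not None else None,
                               cov=True)
        slope_se, intercept_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        cov_si = float(cov[0, 1])
    else:
        coef = np.polyfit(v, i, 1)
        slope_se = intercept_se = cov_si = 0.0
    slope, intercept = float(coef[0]), float(coef[1])
    if slope == 0.0:
        raise ValueError("degenerate fit: zero slope, no reversal potential")
    erev = -intercept / slope
    # delta-method SE for the crossing -b/m
    if slope_se or intercept_se:
        erev_var = (
            (intercept_se / slope) ** 2
            + (intercept * slope_se / slope**2) ** 2
            - 2.0 * intercept / slope**3 * cov_si
        )
        erev_se = float(np.sqrt(max(erev_var, 0.0)))
    else:
        erev_se = 0.0
    residuals = i - (slope * v + intercept)
    return ConductanceFit(
        conductance=slope * 1000.0,
        erev=erev,
        conductance_se=slope_se * 1000.0,
        erev_se=erev_se,
        residuals=residuals,
        n_points=len(points),
    )


def _hyperbola(a, g_max, k_a):
    return g_max * a / (k_a + a)


def fit_binding_hyperbola(
    points: list[tuple[float, float]], weights: np.ndarray | None = None
) -> SaturationFit:
    """Least-squares fit of the single-site binding hyperbola.

    ``points`` are (activity mM, conductance pS) pairs. Three deterministic
    multi-starts guard against the flat likelihood of near-linear data
    (K_a far above the tested range); parameters are bounded positive. A fit
    that fails from every start is returned flagged non-converged with the
    best parameters found.
    """
    if len(points) < 3:
        raise ValueError("need at least three (activity, conductance) points")
    a = np.array([p[0] for p in points], dtype=float)
    g = np.array([p[1] for p in points], dtype=float)
    if np.unique(a).size < 2:
        raise ValueError("need at least two distinct activities")
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, float))
    g_top = float(g.max())
    a_mid = float(np.median(a))
    a_top = float(a.max())
    starts = [
        (g_top, a_mid),
        (2.0 * g_top, a_top),
        (10.0 * g_top, 10.0 * a_top),
    ]
    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                _hyperbola, a, g, p0=p0, sigma=sigma,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((g - _hyperbola(a, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        return SaturationFit(
            g_max=float("nan"), k_a=float("nan"), g_max_se=float("nan"),
            k_a_se=float("nan"), converged=False,
        )
    _, popt, pcov = best
    perr = np.sqrt(np.diag(pcov))
    return SaturationFit(
        g_max=float(popt[0]),
        k_a=float(popt[1]),
        g_max_se=float(perr[0]),
        k_a_se=float(perr[1]),
        converged=True,
        residuals=g - _hyperbola(a, *popt),
    )
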