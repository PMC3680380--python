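"""Trace idealization: Baum-Welch HMM route and 50%-threshold route.

The HMM route models the sampled current as a hidden Markov chain over
occupancy levels 0..L with Gaussian emissions (shared noise SD), fits it by
the Baum-Welch expectation-maximization algorithm (scaled forward-backward,
log-likelihood non-decreasing by construction) and decodes the
maximum-a-posteriori level path with the Viterbi algorithm. The threshold
route is the conventional comparator: sample-wise classification by 50%
thresholds at (k - 1/2) * i_unit.

The forward/backward/Viterbi inner loops are JIT-compiled with numba; the
module degrades to pure-Python loops if numba is unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .records import IdealizedRecord, RawTrace, Segment

try:  # pragma: no cover - numba is an ordinary dependency
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "EmissionModel",
    "HmmFit",
    "init_emission",
    "baum_welch",
    "forward_loglikelihood",
    "viterbi",
    "threshold_idealize",
    "posterior_marginals",
]

NOISE_SD_FLOOR = 1e-3  # pA


@dataclass
class EmissionModel:
    """Gaussian emission model: one mean per occupancy level, shared SD.

    Levels are ordered by increasing |mean| (level 0 = baseline). With
    constraint="linear" the means are tied to mean_k = k * i_unit.
    ``fallback`` flags that initialization could not resolve the requested
    number of modes and used linear spacing between the trace extremes.
    """

    level_means: np.ndarray  # pA
    noise_sd: float  # pA
    constraint: str = "free"
    fallback: bool = False

    def __post_init__(self) -> None:
        self.level_means = np.asarray(self.level_means, dtype=float)
        if self.constraint not in ("free", "linear"):
            raise ValueError("constraint must be 'free' or 'linear'")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        mags = np.abs(self.level_means)
        if self.level_means.size > 1 and np.any(np.diff(mags) < 0):
            raise ValueError("level means must be ordered by increasing magnitude")

    @property
    def n_levels(self) -> int:
        return self.level_means.size - 1


@dataclass
class HmmFit:
    """Result of a Baum-Welch fit."""

    emission: EmissionModel
    transition_matrix: np.ndarray  # per-sample-step probabilities
    initial_distribution: np.ndarray
    log_likelihoods: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    variance_floored: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.transition_matrix, dtype=float)
        if np.any(np.abs(a.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        self.transition_matrix = a
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihoods[-1] if self.log_likelihoods else math.nan


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forward_scaled(x, means, var, transmat, initial):
    """Scaled forward pass. Returns (loglik, alpha_hat, scales)."""
    t_len = x.shape[0]
    s_len = means.shape[0]
    alpha = np.empty((t_len, s_len))
    scales = np.empty(t_len)
    norm = 1.0 / math.sqrt(2.0 * math.pi * var)
    inv2v = 0.5 / var
    loglik = 0.0
    for s in range(s_len):
        d = x[0] - means[s]
        b = norm * math.exp(-d * d * inv2v)
        alpha[0, s] = initial[s] * (b if b > 1e-300 else 1e-300)
    c = 0.0
    for s in range(s_len):
        c += alpha[0, s]
    scales[0] = c
    loglik += math.log(c)
    for s in range(s_len):
        alpha[0, s] /= c
    for t in range(1, t_len):
        c = 0.0
        for s in range(s_len):
            acc = 0.0
            for i in range(s_len):
                acc += alpha[t - 1, i] * transmat[i, s]
            d = x[t] - means[s]
            b = norm * math.exp(-d * d * inv2v)
            val = acc * (b if b > 1e-300 else 1e-300)
            alpha[t, s] = val
            c += val
        scales[t] = c
        loglik += math.log(c)
        for s in range(s_len):
            alpha[t, s] /= c
    return loglik, alpha, scales


@njit(cache=True)
def _em_sufficient_stats(x, means, var, transmat, initial):
    """One E-step: returns loglik and the sufficient statistics.

    gamma0 (S,), gamma_sum (S,), gx (S,), gxx (S,), xi_sum (S,S).
    """
    loglik, alpha, scales = _forward_scaled(x, means, var, transmat, initial)
    t_len = x.shape[0]
    s_len = means.shape[0]
    norm = 1.0 / math.sqrt(2.0 * math.pi * var)
    inv2v = 0.5 / var
    beta = np.ones(s_len)
    beta_next = np.empty(s_len)
    b_next = np.empty(s_len)
    gamma0 = np.zeros(s_len)
    gamma_sum = np.zeros(s_len)
    gx = np.zeros(s_len)
    gxx = np.zeros(s_len)
    xi_sum = np.zeros((s_len, s_len))
    # t = T-1 contribution
    for s in range(s_len):
        g = alpha[t_len - 1, s]  # beta = 1
        gamma_sum[s] += g
        gx[s] += g * x[t_len - 1]
        gxx[s] += g * x[t_len - 1] * x[t_len - 1]
    for t in range(t_len - 2, -1, -1):
        for s in range(s_len):
            d = x[t + 1] - means[s]
            b = norm * math.exp(-d * d * inv2v)
            b_next[s] = b if b > 1e-300 else 1e-300
        c_next = scales[t + 1]
        gsum_t = 0.0
        for i in range(s_len):
            acc = 0.0
            for j in range(s_len):
                w = transmat[i, j] * b_next[j] * beta[j] / c_next
                xi_sum[i, j] += alpha[t, i] * w
                acc += w
            beta_next[i] = acc
        for s in range(s_len):
            g = alpha[t, s] * beta_next[s]
            gamma_sum[s] += g
            gx[s] += g * x[t]
            gxx[s] += g * x[t] * x[t]
            if t == 0:
                gamma0[s] = g
        for s in range(s_len):
            beta[s] = beta_next[s]
    return loglik, gamma0, gamma_sum, gx, gxx, xi_sum


@njit(cache=True)
def _posterior_marginals(x, means, var, transmat, initial):
    """Per-sample posterior state probabilities gamma (T,S)."""
    _, alpha, scales = _forward_scaled(x, means, var, transmat, initial)
    t_len = x.shape[0]
    s_len = means.shape[0]
    norm = 1.0 / math.sqrt(2.0 * math.pi * var)
    inv2v = 0.5 / var
    gamma = np.empty((t_len, s_len))
    beta = np.ones(s_len)
    beta_next = np.empty(s_len)
    for s in range(s_len):
        gamma[t_len - 1, s] = alpha[t_len - 1, s]
    for t in range(t_len - 2, -1, -1):
        c_next = scales[t + 1]
        for i in range(s_len):
            acc = 0.0
            for j in range(s_len):
                d = x[t + 1] - means[j]
                b = norm * math.exp(-d * d * inv2v)
                acc += transmat[i, j] * (b if b > 1e-300 else 1e-300) * beta[j]
            beta_next[i] = acc / c_next
        for s in range(s_len):
            gamma[t, s] = alpha[t, s] * beta_next[s]
        for s in range(s_len):
            beta[s] = beta_next[s]
    return gamma


@njit(cache=True)
def _viterbi_path(x, means, var, log_transmat, log_initial):
    """MAP state path; ties broken toward the lower level index."""
    t_len = x.shape[0]
    s_len = means.shape[0]
    lognorm = -0.5 * math.log(2.0 * math.pi * var)
    inv2v = 0.5 / var
    delta = np.empty(s_len)
    delta_new = np.empty(s_len)
    back = np.empty((t_len, s_len), dtype=np.int32)
    for s in range(s_len):
        d = x[0] - means[s]
        delta[s] = log_initial[s] + lognorm - d * d * inv2v
    for t in range(1, t_len):
        for s in range(s_len):
            best = -1.0e308
            arg = 0
            for i in range(s_len):
                v = delta[i] + log_transmat[i, s]
                if v > best:  # strict: earlier (lower) index wins ties
                    best = v
                    arg = i
            d = x[t] - means[s]
            delta_new[s] = best + lognorm - d * d * inv2v
            back[t, s] = arg
        for s in range(s_len):
            delta[s] = delta_new[s]
    best = -1.0e308
    state = 0
    for s in range(s_len):
        if delta[s] > best:
            best = delta[s]
            state = s
    path = np.empty(t_len, dtype=np.int32)
    path[t_len - 1] = state
    for t in range(t_len - 1, 0, -1):
        state = back[t, state]
        path[t - 1] = state
    return path


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _noise_sd_estimate(x: np.ndarray) -> float:
    """Robust noise SD from first differences (insensitive to level jumps)."""
    mad = float(np.median(np.abs(np.diff(x))))
    return max(mad / (0.6745 * math.sqrt(2.0)), NOISE_SD_FLOOR)


def _histogram_peaks(x: np.ndarray, sd: float) -> np.ndarray:
    """Modes of the amplitude histogram, smoothed at the noise scale."""
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    lo, hi = float(x.min()), float(x.max())
    binw = max(sd / 3.0, (hi - lo) / 4000.0)
    edges = np.arange(lo - binw, hi + 2 * binw, binw)
    counts, _ = np.histogram(x, bins=edges)
    smooth = gaussian_filter1d(counts.astype(float), sigma=max(sd / binw, 1.0))
    # prominence, not height: a rare level is an isolated mode with full
    # prominence, while shoulder bumps from filter-transition samples are not
    idx, _ = find_peaks(
        smooth,
        prominence=2e-3 * smooth.max(),
        distance=max(int(2.5 * sd / binw), 1),
    )
    centers = (edges[:-1] + edges[1:]) / 2.0
    if idx.size == 0:
        return np.array([float(x.mean())])
    # order by peak mass, strongest first
    return centers[idx[np.argsort(smooth[idx])[::-1]]]


def init_emission(trace: RawTrace, n_levels: int) -> EmissionModel:
    """Initial emission model from the amplitude histogram.

    Level means start at the modes of the noise-smoothed amplitude
    histogram. When fewer modes than requested levels are distinguishable —
    typical when rare levels are buried — the missing rungs are filled in on
    the equal-spacing ladder anchored at the extreme mode (levels of an
    ensemble of identical channels are equispaced), and the model is
    flagged as a fallback. Each mean is then refined as the average of the
    samples nearest it. Output means are sorted by |mean|.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    x = trace.samples
    if x.size <= 100:
        raise ValueError("trace too short to initialize an emission model")
    k = n_levels + 1
    fallback = False
    if np.ptp(x) == 0.0:
        means = np.full(k, x.mean())
    else:
        sd0 = _noise_sd_estimate(x)
        peaks = _histogram_peaks(x, sd0)
        far = peaks[np.argmax(np.abs(peaks))]
        if abs(far) < 3.0 * sd0:
            # no resolved open level: linear spread between robust extremes
            fallback = True
            means = np.linspace(float(np.quantile(x, 0.003)),
                                float(np.quantile(x, 0.997)), k)
        else:
            # the levels of an ensemble of identical channels sit on an
            # equispaced ladder through 0; score the hypotheses "extreme
            # mode = level j" and keep the one explaining the most modes
            best = None
            for j in range(n_levels, 0, -1):
                i0 = far / j
                lv = np.rint(peaks / i0)
                ok = (
                    (np.abs(peaks - lv * i0) <= 0.2 * abs(i0))
                    & (lv >= 0) & (lv <= n_levels)
                )
                score = len(set(lv[ok]))
                if best is None or score > best[0]:
                    best = (score, i0, lv, ok)
            score, i0, lv, ok = best
            denom = float((lv[ok] ** 2).sum())
            i_unit = float((lv[ok] * peaks[ok]).sum()) / denom if denom > 0 else i0
            means = np.arange(k) * i_unit
            fallback = score < k
        # one assignment-refinement pass (exact for well-separated levels)
        stride = max(x.size // 200_000, 1)
        xs = x[::stride]
        assign = np.argmin(np.abs(xs[:, None] - np.sort(means)[None, :]), axis=1)
        sorted_means = np.sort(means)
        for j in range(k):
            sel = assign == j
            if np.count_nonzero(sel) >= max(10, xs.size // 100_000):
                sorted_means[j] = float(xs[sel].mean())
        means = sorted_means
    # order levels 0..L by magnitude (baseline closest to zero)
    means = means[np.argsort(np.abs(means))]
    # residual SD around nearest mean as the noise estimate
    nearest = means[np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)] \
        if x.size <= 200_000 else None
    if nearest is None:
        idx = np.argmin(np.abs(x[::10, None] - means[None, :]), axis=1)
        resid = x[::10] - means[idx]
    else:
        resid = x - nearest
    noise_sd = max(float(np.std(resid)), NOISE_SD_FLOOR)
    return EmissionModel(level_means=means, noise_sd=noise_sd, fallback=fallback)


def _sticky_transmat(n_states: int, stay: float = 0.99) -> np.ndarray:
    a = np.full((n_states, n_states), (1.0 - stay) / max(n_states - 1, 1))
    np.fill_diagonal(a, stay if n_states > 1 else 1.0)
    return a


def baum_welch(
    trace: RawTrace,
    init: EmissionModel,
    max_iter: int = 50,
    tol: float = 1e-3,
    transmat: np.ndarray | None = None,
) -> HmmFit:
    """Fit the level HMM by Baum-Welch expectation maximization.

    Gaussian emissions over levels 0..L with a shared noise SD; scaled
    forward-backward in the E-step; closed-form M-step. Stops when the
    log-likelihood gain drops below ``tol`` or after ``max_iter`` iterations.
    The log-likelihood trajectory is recorded and is non-decreasing.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = np.ascontiguousarray(trace.samples, dtype=float)
    means = init.level_means.copy()
    var = float(init.noise_sd) ** 2
    n_states = means.size
    a = _sticky_transmat(n_states) if transmat is None else np.array(transmat, float)
    pi = np.full(n_states, 1.0 / n_states)
    levels = np.arange(n_states, dtype=float)

    logliks: list[float] = []
    converged = False
    floored = False
    n_done = 0
    for it in range(max_iter):
        loglik, gamma0, gsum, gx, gxx, xisum = _em_sufficient_stats(
            x, means, var, a, pi
        )
        logliks.append(float(loglik))
        n_done = it + 1
        if it > 0 and logliks[-1] - logliks[-2] < tol:
            converged = True
            break
        # M-step
        pi = np.clip(gamma0, 1e-12, None)
        pi = pi / pi.sum()
        row = xisum.sum(axis=1, keepdims=True)
        a = np.where(row > 0, xisum / np.where(row > 0, row, 1.0), a)
        a = np.clip(a, 1e-12, None)
        a = a / a.sum(axis=1, keepdims=True)
        if init.constraint == "linear":
            denom = float((levels**2 * gsum).sum())
            i_unit = float((levels * gx).sum()) / denom if denom > 0 else 0.0
            means = levels * i_unit
        else:
            means = np.where(gsum > 0, gx / np.where(gsum > 0, gsum, 1.0), means)
        var = float((gxx - 2.0 * means * gx + means**2 * gsum).sum()) / x.size
        if var < NOISE_SD_FLOOR**2:
            var = NOISE_SD_FLOOR**2
            floored = True

    order = np.argsort(np.abs(means))
    means = means[order]
    a = a[np.ix_(order, order)]
    pi = pi[order]
    emission = EmissionModel(
        level_means=means,
        noise_sd=math.sqrt(var),
        constraint=init.constraint,
        fallback=init.fallback,
    )
    return HmmFit(
        emission=emission,
        transition_matrix=a,
        initial_distribution=pi,
        log_likelihoods=logliks,
        n_iterations=n_done,
        converged=converged,
        variance_floored=floored,
    )


def forward_loglikelihood(
    trace: RawTrace | np.ndarray,
    emission: EmissionModel,
    transmat: np.ndarray,
    initial: np.ndarray,
) -> float:
    """Forward-algorithm log-likelihood of a trace under fixed parameters."""
    x = trace.samples if isinstance(trace, RawTrace) else np.asarray(trace, float)
    ll, _, _ = _forward_scaled(
        np.ascontiguousarray(x),
        emission.level_means,
        float(emission.noise_sd) ** 2,
        np.ascontiguousarray(transmat, dtype=float),
        np.ascontiguousarray(initial, dtype=float),
    )
    return float(ll)


def posterior_marginals(trace: RawTrace, fit: HmmFit) -> np.ndarray:
    """Per-sample posterior level probabilities (rows sum to 1)."""
    return _posterior_marginals(
        np.ascontiguousarray(trace.samples),
        fit.emission.level_means,
        float(fit.emission.noise_sd) ** 2,
        np.ascontiguousarray(fit.transition_matrix),
        np.ascontiguousarray(fit.initial_distribution),
    )


def _rle_to_record(
    path: np.ndarray, sample_rate: float, source: str, level_means=None, **meta
) -> IdealizedRecord:
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [path.size]])
    segments = [
        Segment(int(s) / sample_rate, int(e - s) / sample_rate, int(path[s]))
        for s, e in zip(starts, ends)
    ]
    return IdealizedRecord(
        segments=segments, source=source, level_means=level_means, metadata=meta
    )


def viterbi(trace: RawTrace, fit: HmmFit, method: str = "viterbi") -> IdealizedRecord:
    """Decode the trace into an IdealizedRecord.

    method="viterbi" gives the MAP path; method="posterior" the per-sample
    argmax of the forward-backward marginals. Ties go to the lower level.
    """
    x = np.ascontiguousarray(trace.samples)
    if method == "viterbi":
        path = _viterbi_path(
            x,
            fit.emission.level_means,
            float(fit.emission.noise_sd) ** 2,
            np.log(np.clip(fit.transition_matrix, 1e-300, None)),
            np.log(np.clip(fit.initial_distribution, 1e-300, None)),
        )
    elif method == "posterior":
        gamma = posterior_marginals(trace, fit)
        path = gamma.argmax(axis=1)  # argmax takes the first (lower) on ties
    else:
        raise ValueError("method must be 'viterbi' or 'posterior'")
    return _rle_to_record(
        np.asarray(path),
        trace.sample_rate,
        "hmm",
        level_means=fit.emission.level_means.copy(),
        decode=method,
    )


def hmm_idealize(
    trace: RawTrace,
    n_levels: int,
    max_iter: int = 50,
    tol: float = 1e-3,
    constraint: str = "free",
) -> tuple[IdealizedRecord, HmmFit]:
    """Convenience pipeline: init -> Baum-Welch -> Viterbi."""
    init = init_emission(trace, n_levels)
    init.constraint = constraint
    if constraint == "linear":
        # project the initial means onto the linear form
        lv = np.arange(n_levels + 1, dtype=float)
        denom = float((lv**2).sum())
        init.level_means = lv * float((lv * init.level_means).sum()) / denom
    fit = baum_welch(trace, init, max_iter=max_iter, tol=tol)
    return viterbi(trace, fit), fit


def threshold_idealize(trace: RawTrace, i_unit: float, n_levels: int) -> IdealizedRecord:
    """Conventional 50%-threshold idealization.

    Samples are assigned the level k whose band (k -+ 1/2) * i_unit contains
    them — i.e. thresholds at (k - 0.5) * i_unit for k = 1..L — clipped to
    [0, n_levels]. ``i_unit`` is the unitary current in pA (signed).
    """
    if i_unit == 0:
        raise ValueError("i_unit must be nonzero")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    path = np.clip(np.rint(trace.samples / i_unit).astype(int), 0, n_levels)
    return _rle_to_record(path, trace.sample_rate, "threshold", i_unit=i_unit)
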