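"""Delay-compensated coupling statistics between two order-parameter series.

The workflow this module supports: smooth the cos θ and dr series, scan
integer-sample lags for the delay that optimizes their Pearson correlation,
re-compute the correlation at that delay on the overlapping samples only,
and attach a permutation p-value that respects the autocorrelation of MD
time series (circular block rotations, not i.i.d. shuffles).

Sign convention: a positive lag means the second series (dr) trails the
first (cos θ) — ``y(t) ≈ f(x(t − lag))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .model_io import TimeSeries

__all__ = [
    "LagResult",
    "ExtremaSet",
    "ZeroVarianceError",
    "smooth",
    "pearson",
    "estimate_lag",
    "delayed_correlation",
    "lag_significance",
    "find_extrema",
    "autocorrelation_time",
]


class ZeroVarianceError(ValueError):
    """A correlation was requested for a series with no variance."""


@dataclass
class LagResult:
    """Outcome of a lag scan between two series.

    ``lag_ns`` is positive when the second series lags the first;
    ``curve`` holds (lag_ns, r) for every scanned lag with enough overlap.
    """

    lag_ns: float
    r_at_lag: float
    curve: list[tuple[float, float]]
    n_overlap: int
    p_value: float | None = None


@dataclass
class ExtremaSet:
    """Times of local maxima and minima above a prominence threshold."""

    peak_times: np.ndarray
    valley_times: np.ndarray
    prominence_threshold: float


def _require_uniform(series: TimeSeries) -> float:
    try:
        return series.dt
    except ValueError as exc:
        raise ValueError(f"{exc}; resample to a uniform grid first") from exc


def smooth(
    series: TimeSeries, window_ns: float, method: str = "moving_average"
) -> TimeSeries:
    """Centered smoothing with shrinking windows at the edges.

    ``moving_average`` averages over a centered window of
    ``round(window_ns / dt)`` samples (forced odd); near the edges the window
    shrinks symmetrically so no padding values are invented.
    ``savitzky_golay`` fits a cubic in the same window.
    """
    dt = _require_uniform(series)
    w = int(round(window_ns / dt))
    if w < 2:
        raise ValueError(
            f"window {window_ns} ns is below 2 sample intervals (dt={dt} ns)"
        )
    if w > len(series):
        raise ValueError(
            f"window of {w} samples exceeds series length {len(series)}"
        )
    if w % 2 == 0:
        w += 1
    half = w // 2
    v = series.values
    n = len(v)
    if method == "moving_average":
        out = np.empty(n)
        for i in range(n):
            h = min(half, i, n - 1 - i)  # shrink symmetrically at edges
            out[i] = v[i - h : i + h + 1].mean()
    elif method == "savitzky_golay":
        order = min(3, w - 1)
        out = sp_signal.savgol_filter(v, w, order, mode="interp")
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return TimeSeries(series.times.copy(), out, label=series.label, units=series.units)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; zero variance is an error, never a silent 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant series")
    r = sp_stats.pearsonr(x, y).statistic
    return float(np.clip(r, -1.0, 1.0))


def _overlap(x: np.ndarray, y: np.ndarray, lag_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping segments with y shifted back by ``lag_samples``."""
    n = len(x)
    if lag_samples >= 0:
        return x[: n - lag_samples], y[lag_samples:]
    return x[-lag_samples:], y[: n + lag_samples]


def estimate_lag(
    x: TimeSeries,
    y: TimeSeries,
    max_lag_ns: float,
    min_overlap: int = 10,
    objective: str = "max_abs_r",
) -> LagResult:
    """Scan integer-sample lags in ``[-max_lag, +max_lag]`` for the best delay.

    At each lag the Pearson correlation is computed on the overlapping
    samples only.  The returned lag optimizes the objective (default:
    largest ``|r|``); ties go to the smallest ``|lag|``, then negative
    before positive.
    """
    if objective not in ("max_abs_r", "max_r", "min_r"):
        raise ValueError(f"unknown objective {objective!r}")
    dt = _require_uniform(x)
    dt_y = _require_uniform(y)
    if not np.isclose(dt, dt_y) or len(x) != len(y) or not np.allclose(x.times, y.times):
        raise ValueError("series must share one uniform time grid")
    if min_overlap < 3:
        raise ValueError("min_overlap must be at least 3")
    max_lag_samples = int(round(max_lag_ns / dt))
    if max_lag_samples >= len(x):
        raise ValueError("max_lag_ns must be smaller than the series span")

    score = {
        "max_abs_r": lambda r: abs(r),
        "max_r": lambda r: r,
        "min_r": lambda r: -r,
    }[objective]

    # tie-break order: smallest |lag| first, negative before positive
    lags = sorted(range(-max_lag_samples, max_lag_samples + 1), key=lambda L: (abs(L), L))
    best: tuple[float, int, float, int] | None = None  # (score, lag, r, n)
    curve: list[tuple[float, float]] = []
    for L in lags:
        xs, ys = _overlap(x.values, y.values, L)
        if len(xs) < min_overlap:
            continue
        try:
            r = pearson(xs, ys)
        except ZeroVarianceError:
            continue
        curve.append((L * dt, r))
        if best is None or score(r) > best[0]:
            best = (score(r), L, r, len(xs))
    if best is None:
        raise ValueError(
            f"no lag in +/-{max_lag_ns} ns leaves at least {min_overlap} "
            "overlapping samples with variance"
        )
    curve.sort(key=lambda p: p[0])
    _, L, r, n = best
    return LagResult(lag_ns=L * dt, r_at_lag=r, curve=curve, n_overlap=n)


def delayed_correlation(
    x: TimeSeries, y: TimeSeries, lag_ns: float
) -> tuple[float, int]:
    """Correlation after shifting y back by ``lag_ns``, on the overlap only."""
    dt = _require_uniform(x)
    L_exact = lag_ns / dt
    L = int(round(L_exact))
    if abs(L_exact - L) > 1e-9:
        warnings.warn(
            f"lag {lag_ns} ns is not a multiple of the sample interval "
            f"{dt} ns; using nearest sample lag {L * dt} ns",
            stacklevel=2,
        )
    xs, ys = _overlap(x.values, y.values, L)
    if len(xs) < 3:
        raise ValueError(f"overlap of {len(xs)} samples at lag {lag_ns} ns is below 3")
    return pearson(xs, ys), len(xs)


def lag_significance(
    x: TimeSeries,
    y: TimeSeries,
    lag_ns: float,
    n_permutations: int = 999,
    block_len_ns: float | None = None,
    seed: int = 0,
) -> float:
    """Permutation p-value for the delay-compensated correlation.

    The null preserves each series' autocorrelation by circularly rotating
    the overlapped y segment by whole blocks; rotation offsets are drawn in
    ``+k / n-k`` pairs so that (for even ``n_permutations``) the p-value is
    symmetric under exchanging x and y.  ``block_len_ns`` defaults to the
    estimated autocorrelation time of y.

    ``p = (1 + #{|r_perm| >= |r_obs|}) / (n_permutations + 1)``.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations for a meaningful p-value")
    dt = _require_uniform(x)
    if block_len_ns is None:
        block_len_ns = max(autocorrelation_time(y), dt)
    if block_len_ns < dt:
        raise ValueError("block_len_ns must be at least the sample interval")
    L = int(round(lag_ns / dt))
    xs, ys = _overlap(x.values, y.values, L)
    n = len(xs)
    block = max(1, int(round(block_len_ns / dt)))
    n_blocks = n // block
    if n_blocks < 3:
        raise ValueError(
            f"overlap of {n} samples holds only {n_blocks} blocks of "
            f"{block_len_ns} ns; need at least 3"
        )
    r_obs = abs(pearson(xs, ys))

    rng = np.random.default_rng(seed)
    n_pairs = (n_permutations + 1) // 2
    offsets: list[int] = []
    for k in rng.integers(1, n_blocks, size=n_pairs):
        shift = int(k) * block
        offsets.extend((shift, n - shift))
    offsets = offsets[:n_permutations]

    hits = 0
    for shift in offsets:
        r_perm = abs(pearson(xs, np.roll(ys, shift)))
        if r_perm >= r_obs:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def autocorrelation_time(series: TimeSeries) -> float:
    """Time (ns) at which the autocorrelation first drops below 1/e.

    A simple, robust block-length heuristic for the permutation null; returns
    one sample interval for series that decorrelate immediately.
    """
    dt = _require_uniform(series)
    v = series.values - series.values.mean()
    var = np.dot(v, v)
    if var == 0:
        return dt
    n = len(v)
    target = 1.0 / np.e
    for k in range(1, n // 2):
        ac = np.dot(v[:-k], v[k:]) / var
        if ac < target:
            return k * dt
    return (n // 2) * dt


def find_extrema(series: TimeSeries, prominence: float) -> ExtremaSet:
    """Local maxima and minima with at least the given prominence.

    Meant for smoothed series (noisy input yields spurious extrema); the
    matched peaks/valleys of cos θ and dr visualize their coupling.
    """
    v = series.values
    peaks, _ = sp_signal.find_peaks(v, prominence=prominence)
    valleys, _ = sp_signal.find_peaks(-v, prominence=prominence)
    return ExtremaSet(
        peak_times=series.times[peaks],
        valley_times=series.times[valleys],
        prominence_threshold=prominence,
    )
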