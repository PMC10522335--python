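"""Oscillation quantification for uniformly sampled intensity traces.

Covers the measurements used to characterize monologue/dialogue dynamics in
tip-fluorescence recordings and in simulated trajectories: peak detection,
inter-peak-interval statistics (mean +/- sample SD, n), relative-frequency
histograms, Pearson and sliding-window correlation, phase-relation
classification (in-phase / anti-phase / uncoordinated) and the
transition-slowing ratio.

Statistics that are undefined for an input (fewer than two peaks, zero
variance, ...) are explicitly marked ``None`` rather than silently returned
as 0 or NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _signal

__all__ = [
    "Trace",
    "PeakSeries",
    "IntervalStatistics",
    "Histogram",
    "PhaseClassification",
    "detect_peaks",
    "interval_statistics",
    "relative_frequency_histogram",
    "pearson_correlation",
    "windowed_correlation",
    "phase_relation",
    "slowdown_statistic",
]


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled intensity time series.

    ``time_unit`` is "s" for experimental-scale traces (seconds) or "model"
    for simulation time units (minutes); it selects sensible peak-detection
    defaults but carries no other semantics.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    time_unit: str = "s"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if not np.all(np.isfinite(v)) or not np.all(np.isfinite(t)):
            raise ValueError("trace contains non-finite entries")
        if len(t) >= 2:
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            dt = steps[0]
            if np.any(np.abs(steps - dt) > 1e-9 * max(abs(dt), 1.0)):
                raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("trace has fewer than 2 samples")
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def window(self, t0: float, t1: float) -> "Trace":
        """Sub-trace with times in [t0, t1]."""
        m = (self.times >= t0) & (self.times <= t1)
        return Trace(self.times[m], self.values[m], self.label, self.time_unit)


@dataclass(frozen=True)
class PeakSeries:
    """Detected peak times with their prominences and the options used."""

    peak_times: np.ndarray
    prominences: np.ndarray
    options: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.peak_times)


@dataclass(frozen=True)
class IntervalStatistics:
    """Inter-peak intervals and their mean / sample SD / count.

    ``mean`` is None with fewer than one interval; ``sd`` (n-1 denominator)
    is None with fewer than two.
    """

    intervals: np.ndarray
    mean: Optional[float]
    sd: Optional[float]
    n: int


@dataclass(frozen=True)
class Histogram:
    """Left-closed right-open relative-frequency histogram."""

    bin_edges: np.ndarray
    relative_frequencies: np.ndarray


@dataclass(frozen=True)
class PhaseClassification:
    """Phase relation of two oscillatory traces.

    ``lag_fraction`` is the circular cross-correlation peak lag expressed as
    a fraction of the dominant period, in [0, 1); ``correlation`` is the
    zero-lag Pearson coefficient.
    """

    label: str
    lag_fraction: Optional[float]
    correlation: Optional[float]
    note: str = ""


def _default_min_distance(trace: Trace) -> float:
    return 0.5 if trace.time_unit == "model" else 30.0


def detect_peaks(trace: Trace, min_prominence_fraction: float = 0.2,
                 min_distance: Optional[float] = None,
                 detrend: bool = True) -> PeakSeries:
    """Detect strict local maxima of a (optionally detrended) trace.

    A candidate must have prominence >= ``min_prominence_fraction`` times the
    range of the detrended trace.  When two candidates are closer than
    ``min_distance`` (same time unit as the trace; defaults: 30 s for
    experimental traces, 0.5 time units for model traces) the more prominent
    one is kept, greedily in order of decreasing prominence.
    """
    if not (0 < min_prominence_fraction < 1):
        raise ValueError("min_prominence_fraction must be in (0, 1)")
    opts = {"min_prominence_fraction": min_prominence_fraction,
            "min_distance": min_distance, "detrend": detrend}
    if len(trace.times) < 3:
        warnings.warn("trace shorter than 3 samples: no peaks detectable")
        return PeakSeries(np.empty(0), np.empty(0), opts)
    if min_distance is None:
        min_distance = _default_min_distance(trace)
        opts["min_distance"] = min_distance
    if min_distance < trace.dt:
        raise ValueError("min_distance must be >= the sampling interval")

    x = trace.values.astype(float)
    if detrend:
        x = _signal.detrend(x, type="linear")
    rng = float(np.ptp(x))
    if rng == 0.0:
        return PeakSeries(np.empty(0), np.empty(0), opts)

    idx, props = _signal.find_peaks(x, prominence=min_prominence_fraction * rng)
    if len(idx) == 0:
        return PeakSeries(np.empty(0), np.empty(0), opts)
    prom = props["prominences"]
    # greedy pruning by prominence under the minimum-separation constraint
    order = np.argsort(-prom, kind="stable")
    t = trace.times[idx]
    kept: list[int] = []
    for j in order:
        if all(abs(t[j] - t[kk]) >= min_distance for kk in kept):
            kept.append(j)
    kept.sort(key=lambda j: t[j])
    return PeakSeries(t[kept], prom[kept], opts)


def interval_statistics(peaks: PeakSeries) -> IntervalStatistics:
    """Successive peak-time differences with mean, sample SD and count."""
    iv = np.diff(np.asarray(peaks.peak_times, dtype=float))
    n = len(iv)
    mean = float(iv.mean()) if n >= 1 else None
    sd = float(iv.std(ddof=1)) if n >= 2 else None
    return IntervalStatistics(intervals=iv, mean=mean, sd=sd, n=n)


def relative_frequency_histogram(stats: IntervalStatistics, bin_width: float = 20.0,
                                 origin: float = 0.0) -> Histogram:
    """Relative-frequency histogram of inter-peak intervals.

    Bins are ``[origin + k*bin_width, origin + (k+1)*bin_width)`` spanning
    the observed intervals; frequencies sum to 1 when any interval exists.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if stats.n == 0:
        return Histogram(np.empty(0), np.empty(0))
    iv = stats.intervals
    k = np.floor((iv - origin) / bin_width).astype(int)
    k0, k1 = int(k.min()), int(k.max())
    counts = np.bincount(k - k0, minlength=k1 - k0 + 1)
    edges = origin + bin_width * np.arange(k0, k1 + 2)
    return Histogram(edges, counts / counts.sum())


def _window_mask(times: np.ndarray, window) -> np.ndarray:
    if window is None:
        return np.ones(len(times), dtype=bool)
    t0, t1 = window
    return (times >= t0) & (times <= t1)


def pearson_correlation(a: Trace, b: Trace, window=None) -> Optional[float]:
    """Pearson coefficient of two traces on an identical grid.

    Returns None (explicitly undefined) when either trace has zero variance
    over the window.
    """
    ma, mb = _window_mask(a.times, window), _window_mask(b.times, window)
    ta, tb = a.times[ma], b.times[mb]
    if ta.shape != tb.shape or (len(ta) and not np.allclose(ta, tb, rtol=0, atol=1e-9)):
        raise ValueError("traces must share an identical sampling grid over the window")
    if len(ta) < 2:
        return None
    va, vb = a.values[ma], b.values[mb]
    if va.std() == 0.0 or vb.std() == 0.0:
        return None
    return float(np.corrcoef(va, vb)[0, 1])


def windowed_correlation(a: Trace, b: Trace, window_length: float,
                         step: Optional[float] = None):
    """Sliding-window Pearson correlation series.

    Returns ``(centers, correlations)``; windows where the coefficient is
    undefined are marked NaN.  ``step`` defaults to ``window_length / 4``.
    A window of at least two dominant periods is recommended.
    """
    if window_length <= 0:
        raise ValueError("window_length must be > 0")
    step = window_length / 4 if step is None else step
    if step <= 0:
        raise ValueError("step must be > 0")
    t0, t1 = float(a.times[0]), float(a.times[-1])
    starts = []
    s = t0
    while s + window_length <= t1 + 1e-9:
        starts.append(s)
        s += step
    centers = np.array([s + window_length / 2 for s in starts])
    corrs = np.full(len(starts), np.nan)
    for i, s in enumerate(starts):
        c = pearson_correlation(a, b, window=(s, s + window_length))
        if c is not None:
            corrs[i] = c
    return centers, corrs


def phase_relation(a: Trace, b: Trace, min_prominence_fraction: float = 0.2,
                   min_distance: Optional[float] = None,
                   detrend: bool = True) -> PhaseClassification:
    """Classify two traces as in-phase, anti-phase or uncoordinated.

    The dominant period is the mean inter-peak interval of ``a``; the lag is
    the argmax of the circular cross-correlation within one period,
    expressed as a fraction of the period.  Labels: in-phase for
    lag_fraction in [0, 0.15] or [0.85, 1), anti-phase for [0.35, 0.65] —
    each additionally requiring |zero-lag correlation| >= 0.3 — and
    uncoordinated otherwise (or when either trace shows fewer than 3 peaks).
    """
    pa = detect_peaks(a, min_prominence_fraction, min_distance, detrend)
    pb = detect_peaks(b, min_prominence_fraction, min_distance, detrend)
    if pa.n < 3 or pb.n < 3:
        return PhaseClassification(
            "uncoordinated", None, pearson_correlation(a, b),
            note=f"non-oscillatory input ({pa.n} and {pb.n} peaks)")
    period = float(np.mean(np.diff(pa.peak_times)))
    dt = a.dt
    n_lag = max(1, int(round(period / dt)))
    va = a.values - a.values.mean()
    vb = b.values - b.values.mean()
    denom = np.sqrt((va ** 2).sum() * (vb ** 2).sum())
    if denom == 0.0:
        return PhaseClassification("uncoordinated", None, None, note="zero variance")
    cc = np.array([(va * np.roll(vb, -lag)).sum() / denom for lag in range(n_lag)])
    lag_fraction = (np.argmax(cc) * dt / period) % 1.0
    corr = pearson_correlation(a, b)
    label = "uncoordinated"
    if corr is not None and abs(corr) >= 0.3:
        if lag_fraction <= 0.15 or lag_fraction >= 0.85:
            label = "in-phase"
        elif 0.35 <= lag_fraction <= 0.65:
            label = "anti-phase"
    return PhaseClassification(label, float(lag_fraction), corr)


def _pooled_window_intervals(peaks: Sequence[PeakSeries], window) -> np.ndarray:
    t0, t1 = window
    pooled = []
    for p in peaks:
        pt = np.asarray(p.peak_times, dtype=float)
        pt = pt[(pt >= t0) & (pt <= t1)]
        if len(pt) >= 2:
            pooled.append(np.diff(pt))
    return np.concatenate(pooled) if pooled else np.empty(0)


def slowdown_statistic(peaks_a: PeakSeries, peaks_b: PeakSeries,
                       pre_window, transition_window, post_window) -> Optional[float]:
    """Transition-window slowing ratio of the inter-peak interval.

    Pools the intervals of both series within each window; the statistic is
    the transition-window mean interval divided by the average of the pre-
    and post-window mean intervals.  A ratio > 1 indicates slowing.  Returns
    None when any window lacks two peaks in both series.
    """
    means = []
    for w in (pre_window, transition_window, post_window):
        iv = _pooled_window_intervals((peaks_a, peaks_b), w)
        if len(iv) == 0:
            return None
        means.append(float(iv.mean()))
    pre, trans, post = means
    return trans / ((pre + post) / 2.0)
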