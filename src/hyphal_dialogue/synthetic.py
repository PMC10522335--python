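"""Synthetic fluorescence-trace generation.

Surrogate pulse trains with the statistical structure of tip-fluorescence
recordings: jittered inter-pulse intervals (truncated normal), Gaussian
pulse shapes, optional linear photobleaching drift and additive white
noise.  Defaults follow the measured dialogue-phase period of 104 +/- 28 s.
Pairs can be generated anti-phasic (dialogue), in-phase, or independent
(two monologues), and three-segment entrainment sequences emulate the
uncoordinated -> slowed -> anti-phasic transition.  Ground-truth pulse
centers are always returned so detection and interval statistics can be
validated against them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats as _stats

from .analysis import Trace
from .simulate import Trajectory

__all__ = [
    "PulseTrainSpec",
    "PairSpec",
    "EntrainmentSequence",
    "generate_pulse_trace",
    "generate_pair",
    "generate_entrainment_sequence",
    "trajectory_to_trace",
]


@dataclass(frozen=True)
class PulseTrainSpec:
    """Parameters of one synthetic pulse train (times in seconds).

    Inter-pulse intervals are drawn from a normal distribution truncated
    below at ``2 * pulse_width`` (pulses never overlap); ``pulse_width`` is
    the Gaussian kernel SD.
    """

    period_mean: float = 104.0
    period_sd: float = 28.0
    n_pulses: int = 20
    pulse_width: float = 10.0
    amplitude: float = 1.0
    baseline: float = 0.0
    drift_slope: float = 0.0
    noise_sd: float = 0.0
    sample_interval: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.period_mean <= 2 * self.pulse_width:
            errors.append("period_mean must exceed 2 * pulse_width")
        if self.sample_interval > self.period_mean / 10:
            errors.append("sample_interval must be <= period_mean / 10")
        for name in ("period_sd", "pulse_width", "amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        if self.sample_interval <= 0:
            errors.append("sample_interval must be > 0")
        if self.n_pulses < 1:
            errors.append("n_pulses must be >= 1")
        if errors:
            raise ValueError("invalid PulseTrainSpec: " + "; ".join(errors))

    def replace(self, **changes) -> "PulseTrainSpec":
        return replace(self, **changes)


@dataclass(frozen=True)
class PairSpec:
    """A pair of pulse trains on a common grid.

    ``phase_offset_fraction`` places train 2 relative to train 1 in units of
    the period (0.5 = anti-phase, 0 = in-phase).  With ``shared_jitter``
    both trains share one interval realization, so a 0.5 offset puts each
    train-2 pulse exactly midway between consecutive train-1 pulses;
    otherwise train 2 draws its own intervals (uncoordinated pair).
    """

    base: PulseTrainSpec = PulseTrainSpec()
    phase_offset_fraction: float = 0.5
    shared_jitter: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.phase_offset_fraction < 1):
            raise ValueError("phase_offset_fraction must be in [0, 1)")


def _draw_intervals(rng: np.random.Generator, mean: float, sd: float,
                    lower: float, n: int) -> np.ndarray:
    if n <= 0:
        return np.empty(0)
    if sd == 0:
        return np.full(n, mean)
    a = (lower - mean) / sd
    return _stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n,
                                random_state=rng)


def _render(times: np.ndarray, centers: np.ndarray, spec: PulseTrainSpec,
            rng: Optional[np.random.Generator], label: str) -> Trace:
    v = np.full(len(times), float(spec.baseline)) + spec.drift_slope * times
    w = spec.pulse_width
    for c in centers:
        m = np.abs(times - c) <= 5 * w
        v[m] += spec.amplitude * np.exp(-((times[m] - c) ** 2) / (2 * w * w))
    if spec.noise_sd > 0:
        if rng is None:
            raise ValueError("rng required for noisy rendering")
        v += rng.normal(0.0, spec.noise_sd, size=len(times))
    return Trace(times, v, label=label, time_unit="s")


def _grid(t_end: float, sample_interval: float) -> np.ndarray:
    n = int(math.floor(t_end / sample_interval)) + 1
    return np.arange(n) * sample_interval


def generate_pulse_trace(spec: PulseTrainSpec) -> tuple[Trace, np.ndarray]:
    """One pulse train; returns the trace and the ground-truth pulse centers.

    The first pulse sits one mean period after t=0 and the grid extends
    three pulse widths beyond the last pulse.  Reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    intervals = _draw_intervals(rng, spec.period_mean, spec.period_sd,
                                2 * spec.pulse_width, spec.n_pulses - 1)
    centers = spec.period_mean + np.concatenate([[0.0], np.cumsum(intervals)])
    times = _grid(centers[-1] + 3 * spec.pulse_width, spec.sample_interval)
    return _render(times, centers, spec, rng, "synthetic pulse train"), centers


def generate_pair(pair: PairSpec) -> tuple[Trace, Trace]:
    """Two pulse trains on a common grid per ``pair``.

    Use :func:`generate_pair_with_truth` for the ground-truth centers.
    """
    t1, t2, _, _ = generate_pair_with_truth(pair)
    return t1, t2


def generate_pair_with_truth(pair: PairSpec) -> tuple[Trace, Trace, np.ndarray, np.ndarray]:
    spec = pair.base
    rng = np.random.default_rng(spec.seed)
    frac = pair.phase_offset_fraction
    iv1 = _draw_intervals(rng, spec.period_mean, spec.period_sd,
                          2 * spec.pulse_width, spec.n_pulses - 1)
    c1 = spec.period_mean + np.concatenate([[0.0], np.cumsum(iv1)])
    if pair.shared_jitter:
        # offset within each realized cycle so a 0.5 offset bisects intervals
        next_gap = np.concatenate([iv1, [spec.period_mean]])
        c2 = c1 + frac * next_gap
    else:
        rng2 = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
        iv2 = _draw_intervals(rng2, spec.period_mean, spec.period_sd,
                              2 * spec.pulse_width, spec.n_pulses - 1)
        c2 = spec.period_mean * (1 + frac) + np.concatenate([[0.0], np.cumsum(iv2)])
    t_end = max(c1[-1], c2[-1]) + 3 * spec.pulse_width
    times = _grid(t_end, spec.sample_interval)
    tr1 = _render(times, c1, spec, rng, "tip 1")
    tr2 = _render(times, c2, spec, rng, "tip 2")
    return tr1, tr2, c1, c2


@dataclass(frozen=True)
class EntrainmentSequence:
    """Three-segment surrogate of the monologue -> entrainment -> dialogue
    transition, with ground truth."""

    trace1: Trace
    trace2: Trace
    change_points: tuple[float, float]
    centers1: np.ndarray
    centers2: np.ndarray


def _centers_in_window(rng, mean, sd, lower, t0, t1, start_phase) -> np.ndarray:
    out = []
    t = t0 + start_phase
    while t < t1:
        out.append(t)
        t += float(_draw_intervals(rng, mean, sd, lower, 1)[0])
    return np.asarray(out)


def generate_entrainment_sequence(pre: PairSpec, transition_slowdown_factor: float,
                                  post: PairSpec,
                                  segment_durations: tuple[float, float, float],
                                  ) -> EntrainmentSequence:
    """Concatenate uncoordinated, slowed-uncoordinated and anti-phasic
    segments.

    Segment 1 follows ``pre`` (independent jitter), segment 2 repeats it
    with the period scaled by ``transition_slowdown_factor`` (>= 1), and
    segment 3 follows ``post`` (anti-phasic construction).  Returns both
    traces, the two change points, and the ground-truth pulse centers.
    """
    if transition_slowdown_factor < 1:
        raise ValueError("transition_slowdown_factor must be >= 1")
    d1, d2, d3 = segment_durations
    if min(d1, d2, d3) <= 0:
        raise ValueError("segment durations must be > 0")
    spec = pre.base
    lower = 2 * spec.pulse_width
    ss = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
    t1_end, t2_end = d1, d1 + d2

    f = transition_slowdown_factor
    c1 = [
        _centers_in_window(rngs[0], spec.period_mean, spec.period_sd, lower,
                           0.0, t1_end, spec.period_mean),
        _centers_in_window(rngs[1], f * spec.period_mean, f * spec.period_sd,
                           lower, t1_end, t2_end, 0.5 * f * spec.period_mean),
    ]
    c2 = [
        _centers_in_window(rngs[2], spec.period_mean, spec.period_sd, lower,
                           0.0, t1_end, 1.4 * spec.period_mean),
        _centers_in_window(rngs[3], f * spec.period_mean, f * spec.period_sd,
                           lower, t1_end, t2_end, 0.8 * f * spec.period_mean),
    ]
    # anti-phasic final segment: shared realization, offset by the fraction
    pspec = post.base
    iv3 = _draw_intervals(rngs[4], pspec.period_mean, pspec.period_sd,
                          2 * pspec.pulse_width,
                          int(math.ceil(d3 / pspec.period_mean)) + 3)
    a = t2_end + 0.5 * pspec.period_mean + np.concatenate([[0.0], np.cumsum(iv3)])
    next_gap = np.concatenate([iv3, [pspec.period_mean]])
    b = a + post.phase_offset_fraction * next_gap
    total = d1 + d2 + d3
    c1.append(a[a < total])
    c2.append(b[b < total])
    cc1, cc2 = np.concatenate(c1), np.concatenate(c2)

    times = _grid(total, spec.sample_interval)
    rng_noise = np.random.default_rng(ss.spawn(1)[0])
    tr1 = _render(times, cc1, spec, rng_noise, "tip 1")
    tr2 = _render(times, cc2, spec, rng_noise, "tip 2")
    return EntrainmentSequence(tr1, tr2, (t1_end, t2_end), cc1, cc2)


def trajectory_to_trace(traj: Trajectory, cell: int, variable: str,
                        gain: float = 1.0, offset: float = 0.0,
                        noise_sd: float = 0.0,
                        sample_interval: Optional[float] = None,
                        seed: Optional[int] = None,
                        seconds_per_unit: Optional[float] = None) -> Trace:
    """Convert one simulated variable into a pseudo-fluorescence trace.

    Applies ``gain * value + offset``, optional additive white noise, and
    optional downsampling (``sample_interval`` must be an integer multiple
    of the trajectory's recording spacing).  With ``seconds_per_unit`` set
    (e.g. 60), trace times are converted to seconds; otherwise they stay in
    model time units.
    """
    rec_dt = float(traj.times[1] - traj.times[0])
    if sample_interval is None:
        stride = 1
    else:
        ratio = sample_interval / rec_dt
        stride = int(round(ratio))
        if stride < 1 or abs(ratio - stride) > 1e-9:
            raise ValueError(
                "sample_interval must be a positive integer multiple of the "
                f"recording spacing {rec_dt}")
    t = traj.times[::stride]
    v = gain * traj.series(cell, variable)[::stride] + offset
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=len(v))
    if seconds_per_unit is not None:
        return Trace(t * seconds_per_unit, v, label=f"{variable}{cell}",
                     time_unit="s")
    return Trace(t, v, label=f"{variable}{cell}", time_unit="model")
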