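"""The model's in-silico experiments.

Five canned numerical experiments characterize the monologue/dialogue
behavior of the coupled two-cell model: a single-cell run (monologue), a
fixed-distance run with phase classification (independence at long
distance, anti-phase dialogue at short distance), a distance sweep of the
activator-activator Pearson correlation, an approach ramp showing
entrainment with transient slowing, and media depletion abolishing
oscillations.  All are thin, reproducible drivers around
:func:`hyphal_dialogue.simulate.simulate` and the trace-analysis layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .analysis import (
    PhaseClassification,
    Trace,
    detect_peaks,
    interval_statistics,
    pearson_correlation,
    phase_relation,
    slowdown_statistic,
    windowed_correlation,
)
from .model import ModelParameters
from .simulate import DistanceSchedule, SimulationSettings, Trajectory, simulate

__all__ = [
    "SweepResult",
    "OscillationReport",
    "RampResult",
    "run_single_cell",
    "run_fixed_distance",
    "run_distance_sweep",
    "run_approach_ramp",
    "run_media_depletion",
]

#: peaks per 100 time units required to call a trace oscillatory
OSCILLATION_PEAK_RATE = 5.0


def _activator_trace(traj: Trajectory, cell: int) -> Trace:
    return Trace(traj.times, traj.series(cell, "A"), label=f"A{cell}",
                 time_unit="model")


def _seed_list(base_seed: int, n: int) -> list[int]:
    return [int((base_seed + j) % 2**31) for j in range(n)]


def run_single_cell(params: ModelParameters | None = None,
                    settings: SimulationSettings | None = None) -> Trajectory:
    """Simulate one isolated cell (monologue).

    Realized as the two-cell system with the tip-to-tip coupling forced to
    zero (the two cells are then statistically independent replicas); cell 1
    is the one to analyze.
    """
    params = params if params is not None else ModelParameters()
    # kz only enters through kz*exp(-d); the smallest positive value
    # decouples the cells without violating the kz > 0 invariant
    decoupled = params.replace(kz=np.finfo(float).tiny)
    return simulate(decoupled, settings, DistanceSchedule.constant(decoupled.d))


def run_fixed_distance(d: float, params: ModelParameters | None = None,
                       settings: SimulationSettings | None = None,
                       ) -> tuple[Trajectory, Optional[float], PhaseClassification]:
    """Simulate at constant distance ``d``; report the post-burn-in Pearson
    correlation of the two activators and their phase classification."""
    if d < 0:
        raise ValueError("d must be >= 0")
    params = params if params is not None else ModelParameters()
    traj = simulate(params.replace(d=float(d)), settings,
                    DistanceSchedule.constant(float(d)))
    a1, a2 = _activator_trace(traj, 1), _activator_trace(traj, 2)
    return traj, pearson_correlation(a1, a2), phase_relation(a1, a2)


@dataclass
class SweepResult:
    """Distance sweep of the activator anti-correlation."""

    d_values: np.ndarray
    seeds: list[int]
    correlations: np.ndarray        # shape (len(d_values), len(seeds))
    summary_mean: np.ndarray
    summary_sd: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        rows = [(d, s, self.correlations[i, j])
                for i, d in enumerate(self.d_values)
                for j, s in enumerate(self.seeds)]
        return pd.DataFrame(rows, columns=["d", "seed", "correlation"])


def run_distance_sweep(d_grid: Sequence[float], n_seeds: int = 10,
                       params: ModelParameters | None = None,
                       settings: SimulationSettings | None = None) -> SweepResult:
    """Per-distance, per-seed Pearson correlation of A1 vs A2.

    Seeds are ``settings.seed + j`` for j = 0..n_seeds-1, shared across
    distances so per-distance differences are not confounded by the noise
    realization set.
    """
    d_grid = np.asarray(list(d_grid), dtype=float)
    if len(d_grid) == 0:
        raise ValueError("d_grid must be nonempty")
    if np.any(np.diff(d_grid) < 0):
        raise ValueError("d_grid must be sorted ascending")
    settings = settings if settings is not None else SimulationSettings()
    seeds = _seed_list(settings.seed, n_seeds)
    corr = np.empty((len(d_grid), n_seeds))
    for i, d in enumerate(d_grid):
        for j, seed in enumerate(seeds):
            _, c, _ = run_fixed_distance(d, params, settings.replace(seed=seed))
            corr[i, j] = np.nan if c is None else c
    sd = (corr.std(axis=1, ddof=1) if n_seeds > 1
          else np.full(len(d_grid), np.nan))
    return SweepResult(d_values=d_grid, seeds=seeds, correlations=corr,
                       summary_mean=corr.mean(axis=1), summary_sd=sd)


@dataclass
class RampResult:
    """Approach-ramp (entrainment) experiment output."""

    trajectory: Trajectory
    window_centers: np.ndarray
    window_correlations: np.ndarray
    slowdown_ratio: Optional[float]
    windows: dict


def run_approach_ramp(schedule: DistanceSchedule,
                      params: ModelParameters | None = None,
                      settings: SimulationSettings | None = None,
                      window_length: float = 10.0) -> RampResult:
    """Simulate a decreasing-distance ramp and quantify entrainment.

    Reports the sliding-window correlation of the two activators and the
    slowdown ratio of pooled inter-peak intervals across the pre-ramp /
    ramp / post-ramp windows.
    """
    settings = settings if settings is not None else SimulationSettings()
    traj = simulate(params, settings, schedule)
    a1, a2 = _activator_trace(traj, 1), _activator_trace(traj, 2)
    centers, corrs = windowed_correlation(a1, a2, window_length)
    if schedule.kind == "linear_ramp":
        pre = (0.0, schedule.ramp_start)
        trans = (schedule.ramp_start, schedule.ramp_end)
        post = (schedule.ramp_end, float(traj.times[-1]))
    else:
        third = float(traj.times[-1]) / 3
        pre, trans, post = (0, third), (third, 2 * third), (2 * third, 3 * third)
    p1, p2 = detect_peaks(a1), detect_peaks(a2)
    ratio = slowdown_statistic(p1, p2, pre, trans, post)
    return RampResult(trajectory=traj, window_centers=centers,
                      window_correlations=corrs, slowdown_ratio=ratio,
                      windows={"pre": pre, "transition": trans, "post": post})


@dataclass(frozen=True)
class OscillationReport:
    """Does a condition sustain oscillations?

    ``oscillating`` is true iff ``peak_count`` reaches
    ``OSCILLATION_PEAK_RATE`` peaks per 100 time units over the analysis
    window (peaks at relative prominence >= 0.2).
    """

    condition: str
    peak_count: int
    mean_amplitude: Optional[float]
    oscillating: bool
    threshold: float


def run_media_depletion(cmedia_values: Sequence[float],
                        params: ModelParameters | None = None,
                        settings: SimulationSettings | None = None,
                        ) -> list[OscillationReport]:
    """Single-cell runs at each bulk-media signaling concentration.

    Lowering ``cmedia`` starves the tip pool Z and should abolish
    oscillations; ``cmedia = 1`` is the control.
    """
    params = params if params is not None else ModelParameters()
    settings = settings if settings is not None else SimulationSettings()
    reports = []
    for cm in cmedia_values:
        if cm < 0:
            raise ValueError("cmedia values must be >= 0")
        traj = run_single_cell(params.replace(cmedia=float(cm)), settings)
        a1 = _activator_trace(traj, 1)
        peaks = detect_peaks(a1)
        threshold = OSCILLATION_PEAK_RATE * settings.total_time / 100.0
        amp = float(np.mean(peaks.prominences)) if peaks.n else None
        reports.append(OscillationReport(
            condition=f"cmedia={cm}", peak_count=peaks.n, mean_amplitude=amp,
            oscillating=peaks.n >= threshold, threshold=threshold))
    return reports
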