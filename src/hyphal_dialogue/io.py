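"""Configuration loading, CSV trace/trajectory I/O and run provenance.

CSV dialect: comma-separated, UTF-8, mandatory header, full float precision
(round-trippable).  Trajectories are written long-format (time, cell,
variable, value) with a JSON metadata sidecar carrying parameters, settings,
schedule and seed — enough to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .analysis import Trace
from .model import ModelParameters
from .simulate import DistanceSchedule, SimulationSettings, Trajectory

__all__ = [
    "AnalysisOptions",
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_trace_csv",
    "read_trace_csv",
]

log = logging.getLogger("hyphal_dialogue")


class ConfigError(ValueError):
    """Configuration file problem, naming the offending field."""


@dataclass(frozen=True)
class AnalysisOptions:
    """Trace-analysis options shared by the CLI subcommands."""

    min_prominence_fraction: float = 0.2
    min_distance: Optional[float] = None
    bin_width: float = 20.0
    window_length: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.min_prominence_fraction < 1):
            raise ConfigError("analysis.min_prominence_fraction must be in (0, 1)")
        if self.bin_width <= 0:
            raise ConfigError("analysis.bin_width must be > 0")
        if self.window_length <= 0:
            raise ConfigError("analysis.window_length must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration."""

    parameters: ModelParameters = ModelParameters()
    settings: SimulationSettings = SimulationSettings()
    schedule: DistanceSchedule = DistanceSchedule.constant(10.0)
    analysis: AnalysisOptions = AnalysisOptions()
    outdir: str = "runs"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.to_dict(),
            "settings": self.settings.to_dict(),
            "schedule": self.schedule.to_dict(),
            "analysis": dataclasses.asdict(self.analysis),
            "outdir": self.outdir,
            "log_level": self.log_level,
        }


_SECTIONS = {"parameters", "settings", "schedule", "analysis", "outdir", "log_level"}


def _build_section(cls, mapping: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {section!r}: {sorted(unknown)}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section!r} section: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load a YAML config; missing keys take defaults, unknown keys are
    rejected with a named-field diagnostic."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    params = _build_section(ModelParameters, raw.get("parameters", {}), "parameters")
    settings = _build_section(SimulationSettings, raw.get("settings", {}), "settings")
    sched_raw = raw.get("schedule")
    if sched_raw is None:
        schedule = DistanceSchedule.constant(params.d)
    else:
        try:
            schedule = DistanceSchedule.from_dict(sched_raw)
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid 'schedule' section: {exc}") from exc
    analysis = _build_section(AnalysisOptions, raw.get("analysis", {}), "analysis")
    cfg = RunConfig(parameters=params, settings=settings, schedule=schedule,
                    analysis=analysis, outdir=str(raw.get("outdir", "runs")),
                    log_level=str(raw.get("log_level", "INFO")))
    log.debug("resolved config: %s", cfg.to_dict())
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# trajectory / trace CSV

def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Long-format CSV plus a ``.meta.json`` sidecar with full provenance."""
    path = Path(path)
    df = traj.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "parameters": traj.params.to_dict(),
        "settings": traj.settings.to_dict(),
        "schedule": traj.schedule.to_dict(),
        "seed": traj.settings.seed,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_trajectory_csv(path) -> Trajectory:
    """Rebuild a Trajectory from the CSV + sidecar written by
    :func:`write_trajectory_csv`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    times = np.sort(df["time"].unique())
    states = np.empty((len(times), 10))
    order = {"A": 0, "I": 1, "X": 2, "Y": 3, "Z": 4}
    idx = {t: i for i, t in enumerate(times)}
    for row in df.itertuples(index=False):
        states[idx[row.time], 5 * (row.cell - 1) + order[row.variable]] = row.value
    return Trajectory(
        times=times, states=states,
        params=ModelParameters.from_dict(meta["parameters"]),
        settings=SimulationSettings(**meta["settings"]),
        schedule=DistanceSchedule.from_dict(meta["schedule"]),
    )


def write_trace_csv(trace: Trace, path) -> None:
    """Columns time, value (and label when present), full precision."""
    df = pd.DataFrame({"time": trace.times, "value": trace.values})
    if trace.label:
        df["label"] = trace.label
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace_csv(path, time_unit: str = "s") -> Trace:
    """Read a trace CSV.  Rejects missing headers and non-uniform grids,
    naming the first offending row."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
    if "time" not in header or "value" not in header:
        raise ValueError(f"{path}: CSV must have a header with 'time' and 'value' columns")
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time"].to_numpy(dtype=float)
    if len(t) >= 2:
        steps = np.diff(t)
        dt = steps[0]
        bad = np.flatnonzero((steps <= 0) | (np.abs(steps - dt) > 1e-9 * max(abs(dt), 1.0)))
        if len(bad):
            raise ValueError(
                f"{path}: non-uniform time grid at row {int(bad[0]) + 3}")
    label = str(df["label"].iloc[0]) if "label" in df.columns and len(df) else ""
    return Trace(t, df["value"].to_numpy(dtype=float), label=label, time_unit=time_unit)
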