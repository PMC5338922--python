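"""Run configuration, validation, and result serialization.

A :class:`RunConfig` mirrors the module parameter sets (stimulus, model,
analysis, synth) and is read from / written to YAML.  Schedules and spike
tables round-trip through plain CSV; structured results are JSON.  Every run
writes a frozen copy of its resolved configuration plus a log of package
versions, seed, and config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import CircuitParams
from .stimulus import GratingSpec, ScheduleEntry, TransitionSchedule

__all__ = [
    "ConfigError",
    "RunConfig",
    "schedule_to_csv",
    "schedule_from_csv",
    "spikes_to_csv",
    "spikes_from_csv",
    "write_run_record",
]

_SCHEDULE_COLUMNS = [
    "entry",
    "start_position",
    "target_position",
    "transition_kind",
    "onset_time",
    "fixation_duration",
    "transition_duration",
    "fixation_contrast",
    "shift_distance",
]


class ConfigError(ValueError):
    """Configuration problem, reported with the offending key path."""


def _build(cls, block: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    stimulus: GratingSpec = field(default_factory=GratingSpec)
    model: CircuitParams = field(default_factory=CircuitParams)
    analysis: dict = field(default_factory=lambda: {
        "bin_ms": 10.0,
        "window": [50.0, 200.0],
        "rate_screen_hz": 50.0,
        "rsi_threshold": 0.5,
    })
    synth: dict = field(default_factory=dict)
    fixation_duration: float = 800.0
    transition_duration: float = 100.0
    transition_kind: str = "saccadic"
    outdir: str = "results"
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "model" not in data:
            raise ConfigError("model: block is missing")
        stimulus = _build(GratingSpec, data.pop("stimulus", {}), "stimulus")
        model = _build(CircuitParams, data.pop("model", {}), "model")
        cfg = cls(stimulus=stimulus, model=model, **data)
        win = cfg.analysis.get("window", [50.0, 200.0])
        if len(win) != 2 or win[0] >= win[1]:
            raise ConfigError("analysis.window: must be [start, stop) with start < stop")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "stimulus": asdict(self.stimulus),
            "model": asdict(self.model),
            "analysis": self.analysis,
            "synth": self.synth,
            "fixation_duration": self.fixation_duration,
            "transition_duration": self.transition_duration,
            "transition_kind": self.transition_kind,
            "outdir": self.outdir,
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def schedule_to_csv(schedule: TransitionSchedule, path: str | Path) -> None:
    """Write a schedule as a CSV event table (times in ms, 3 decimals)."""
    rows = []
    for k, e in enumerate(schedule.entries):
        rows.append({
            "entry": k,
            "start_position": e.start_position,
            "target_position": e.target_position,
            "transition_kind": e.transition_kind,
            "onset_time": round(e.onset_time, 3),
            "fixation_duration": round(e.fixation_duration, 3),
            "transition_duration": round(e.transition_duration, 3),
            "fixation_contrast": e.fixation_contrast,
            "shift_distance": e.shift_distance,
        })
    pd.DataFrame(rows, columns=_SCHEDULE_COLUMNS).to_csv(path, index=False)


def schedule_from_csv(path: str | Path, n_positions: int = 4) -> TransitionSchedule:
    df = pd.read_csv(path)
    missing = set(_SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"schedule CSV missing columns {sorted(missing)}")
    entries = [
        ScheduleEntry(
            start_position=int(r.start_position),
            target_position=int(r.target_position),
            transition_kind=str(r.transition_kind),
            fixation_duration=float(r.fixation_duration),
            transition_duration=float(r.transition_duration),
            fixation_contrast=float(r.fixation_contrast),
            shift_distance=float(r.shift_distance),
            onset_time=float(r.onset_time),
        )
        for r in df.sort_values("entry").itertuples()
    ]
    return TransitionSchedule(entries, n_positions=n_positions)


def spikes_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a spike table (cell_id, trial, time_ms; ms with 3 decimals)."""
    out = table.copy()
    out["time_ms"] = out["time_ms"].round(3)
    out.to_csv(path, index=False)


def spikes_from_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "trial", "time_ms"}
    if not required.issubset(df.columns):
        raise ConfigError(f"spike CSV must have columns {sorted(required)}")
    if df.empty:
        raise ConfigError("spike CSV contains no spikes")
    return df


def write_run_record(config: RunConfig, outdir: str | Path) -> Path:
    """Freeze the resolved config and a provenance log into the output dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.resolved.yaml")
    record = {
        "irsretina_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "config_sha256_16": config.digest(),
    }
    with open(outdir / "run.log.json", "w") as fh:
        json.dump(record, fh, indent=2)
    return outdir
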