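"""File formats: CSV trace files, JSON manifests, YAML run configuration.

Trace files are plain CSV with one header row naming units::

    time_s,thumb_normal_n,index_normal_n,thumb_vertical_n,index_vertical_n
    [,thumb_pos_x_mm,thumb_pos_y_mm,thumb_pos_z_mm,
      index_pos_x_mm,index_pos_y_mm,index_pos_z_mm]

A dataset manifest (JSON) lists every trial file with its condition,
validity, creation seed, and — for synthetic data — the ground-truth block.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .processing import ForceTrace
from .synthetic import LiftSimConfig, ObserverConfig, TrialRecord

__all__ = [
    "SCHEMA_VERSION",
    "TraceSchemaError",
    "RunConfig",
    "write_trace_file",
    "read_trace_file",
    "write_manifest",
    "read_manifest",
]

SCHEMA_VERSION = 1

MANDATORY_COLUMNS = (
    "time_s",
    "thumb_normal_n",
    "index_normal_n",
    "thumb_vertical_n",
    "index_vertical_n",
)
POSITION_COLUMNS = (
    "thumb_pos_x_mm",
    "thumb_pos_y_mm",
    "thumb_pos_z_mm",
    "index_pos_x_mm",
    "index_pos_y_mm",
    "index_pos_z_mm",
)


class TraceSchemaError(ValueError):
    """A trace file violates the column or sampling contract."""


def write_trace_file(trace: ForceTrace, path: str | Path) -> Path:
    """Write a ForceTrace as CSV with unit-bearing column names."""
    path = Path(path)
    cols = {
        "time_s": trace.time,
        "thumb_normal_n": trace.thumb_normal,
        "index_normal_n": trace.index_normal,
        "thumb_vertical_n": trace.thumb_vertical,
        "index_vertical_n": trace.index_vertical,
    }
    if trace.thumb_pos is not None and trace.index_pos is not None:
        for i, axis in enumerate("xyz"):
            cols[f"thumb_pos_{axis}_mm"] = trace.thumb_pos[:, i]
        for i, axis in enumerate("xyz"):
            cols[f"index_pos_{axis}_mm"] = trace.index_pos[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    return path


def read_trace_file(
    path: str | Path,
    mass_g: float | None = None,
    delay_ms: float | None = None,
    participant_id: str | None = None,
    trial_id: str | None = None,
    uniformity_tol: float = 1e-6,
) -> ForceTrace:
    """Parse a trace CSV, checking the schema and time-base uniformity."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise TraceSchemaError(f"{path.name}: missing mandatory column {col!r}")
    time = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(time)
    if time.size < 2 or dt.min() <= 0 or np.max(np.abs(dt - dt[0])) > uniformity_tol:
        raise TraceSchemaError(f"{path.name}: time base is not uniformly sampled")
    thumb_pos = index_pos = None
    if all(c in df.columns for c in POSITION_COLUMNS):
        thumb_pos = df[list(POSITION_COLUMNS[:3])].to_numpy(dtype=float)
        index_pos = df[list(POSITION_COLUMNS[3:])].to_numpy(dtype=float)
    return ForceTrace(
        time=time,
        thumb_normal=df["thumb_normal_n"].to_numpy(dtype=float),
        index_normal=df["index_normal_n"].to_numpy(dtype=float),
        thumb_vertical=df["thumb_vertical_n"].to_numpy(dtype=float),
        index_vertical=df["index_vertical_n"].to_numpy(dtype=float),
        thumb_pos=thumb_pos,
        index_pos=index_pos,
        mass_g=mass_g,
        delay_ms=delay_ms,
        participant_id=participant_id,
        trial_id=trial_id,
    )


def write_manifest(
    path: str | Path,
    dataset_id: str,
    seed: int,
    records: Iterable[tuple[TrialRecord, str]],
) -> Path:
    """Write a dataset manifest; ``records`` pairs each TrialRecord with the
    relative path of its trace file."""
    entries = []
    for rec, rel in records:
        entries.append(
            {
                "file": rel,
                "trial_id": rec.trial_id,
                "participant": rec.participant_id,
                "mass_g": rec.mass_g,
                "delay_ms": rec.delay_ms,
                "valid": rec.valid,
                "invalid_reason": rec.invalid_reason,
                "truth": {
                    "contact_s": rec.truth_contact,
                    "liftoff_s": rec.truth_liftoff,
                    "lf_onset_s": rec.truth_lf_onset,
                    "d_s": rec.truth_d,
                    "w_v": rec.truth_w_v,
                    "model": rec.truth_model,
                },
            }
        )
    ids = [e["trial_id"] for e in entries]
    if len(ids) != len(set(ids)):
        raise ValueError("trial ids in a manifest must be unique")
    payload = {
        "dataset_id": dataset_id,
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "n_trials": len(entries),
        "trials": entries,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_manifest(path: str | Path) -> dict[str, Any]:
    payload = json.loads(Path(path).read_text())
    root = Path(path).parent
    for entry in payload["trials"]:
        if not (root / entry["file"]).exists():
            raise FileNotFoundError(f"manifest lists missing file {entry['file']}")
    return payload


@dataclass
class RunConfig:
    """Everything the pipeline needs: paths, seed, design, and parameters.

    Simulation parameters default to the apparatus constants (500-Hz
    sampling, g = 9.81) and a small two-participant design so that a full
    pipeline run stays fast; scale ``n_no_delay``/``n_delay``/participant
    counts up for full-size experiments.
    """

    outdir: str = "vhlift_out"
    seed: int = 0
    design: str = "exp1"  # "exp1" | "exp2"
    # experiment-1 design
    participants_exp1: int = 2
    masses_g: tuple[float, ...] = (100.0, 200.0, 300.0, 400.0)
    delays_ms: tuple[float, ...] = (100.0, 200.0)
    n_no_delay: int = 4
    n_delay: int = 1
    # experiment-2 design
    participants_exp2: int = 2
    exp2_delay_ms: float = 200.0
    # generative parameters
    sim: dict[str, Any] = field(default_factory=dict)  # LiftSimConfig overrides
    observer: dict[str, Any] = field(default_factory=dict)  # ObserverConfig overrides
    # processing tolerances
    filter_cutoff_hz: float = 15.0
    filter_order: int = 2
    onset_threshold_n: float = 0.1
    drop_fraction: float = 0.5
    start_tolerance_mm: float = 10.0
    # fitting options
    weight_bounds: tuple[float, float] | None = None
    duration_bounds: tuple[float, float] = (0.05, 3.0)

    def lift_config(self, **overrides: Any) -> LiftSimConfig:
        merged = {**self.sim, **overrides}
        return LiftSimConfig(**merged)

    def observer_config(self, **overrides: Any) -> ObserverConfig:
        merged = {**self.observer, **overrides}
        if "delay_heaviness_gain" in merged and isinstance(
            merged["delay_heaviness_gain"], Mapping
        ):
            merged["delay_heaviness_gain"] = {
                float(k): float(v) for k, v in merged["delay_heaviness_gain"].items()
            }
        return ObserverConfig(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("masses_g", "delays_ms", "duration_bounds", "weight_bounds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        for key in ("masses_g", "delays_ms", "duration_bounds", "weight_bounds"):
            if data[key] is not None:
                data[key] = list(data[key])
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path
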