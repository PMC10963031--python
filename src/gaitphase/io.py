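"""Readers and writers for the session's tabular formats.

Input files are plain CSV:

* ``pose.csv`` — ``frame,nose_x,nose_y,tail_x,tail_y,lf_x,lf_y,lr_x,lr_y,
  rf_x,rf_y,rr_x,rr_y`` with coordinates in pixels; converted to mm on
  load so downstream code never sees pixels.
* ``spikes.csv`` — ``unit_id,spike_time_s``.
* ``laser.csv`` — ``onset_s,duration_s``.
* ``waveforms.csv`` — ``unit_id,condition,sample_index,voltage_uv`` with
  condition in {baseline, evoked}.

Output tables (``strides.csv``, ``bouts.csv``, ``cell_metrics.csv``) are
plain CSV accompanied by a YAML run-metadata sidecar recording the full
config and seed for auditability.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SessionConfig
from .types import BODY_PARTS, FormatError, IntegrityError, LaserPulseTrain, PoseTrack, SpikeTrain

__all__ = [
    "read_pose",
    "read_spikes",
    "read_laser",
    "read_waveforms",
    "session_firing_rate",
    "write_table",
    "read_table",
    "write_run_metadata",
]

POSE_COLUMNS = ["frame"] + [f"{p}_{ax}" for p in BODY_PARTS for ax in ("x", "y")]


def read_pose(path, config: SessionConfig) -> PoseTrack:
    """Load a pose CSV (pixels) into a :class:`PoseTrack` (mm)."""
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pose file {path} missing columns: {missing}")
    if len(df) == 0:
        raise IntegrityError(f"pose file {path} has an empty data section")
    frames = df["frame"].to_numpy(dtype=np.int64)
    if np.any(np.diff(frames) != 1):
        raise IntegrityError(f"pose file {path}: frame numbers not gapless/increasing")
    coords = {
        p: df[[f"{p}_x", f"{p}_y"]].to_numpy(dtype=float) * config.mm_per_pixel
        for p in BODY_PARTS
    }
    return PoseTrack(frame_index=frames, coords=coords, frame_rate_hz=config.frame_rate_hz)


def read_spikes(path) -> list[SpikeTrain]:
    """Load ``spikes.csv`` into one sorted :class:`SpikeTrain` per unit."""
    df = pd.read_csv(path, dtype={"unit_id": str})
    for col in ("unit_id", "spike_time_s"):
        if col not in df.columns:
            raise FormatError(f"spikes file {path} missing column {col!r}")
    if (df["spike_time_s"] < 0).any():
        raise ValueError(f"spikes file {path} contains negative spike times")
    n_before = len(df)
    df = df.drop_duplicates(["unit_id", "spike_time_s"])
    if len(df) < n_before:
        warnings.warn(
            f"{path}: dropped {n_before - len(df)} duplicate (unit, time) rows",
            stacklevel=2,
        )
    trains = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        trains.append(SpikeTrain(unit_id=str(unit_id), spike_times_s=grp["spike_time_s"].to_numpy()))
    return trains


def read_laser(path) -> LaserPulseTrain:
    df = pd.read_csv(path)
    for col in ("onset_s", "duration_s"):
        if col not in df.columns:
            raise FormatError(f"laser file {path} missing column {col!r}")
    duration = float(df["duration_s"].iloc[0]) if len(df) else 0.010
    return LaserPulseTrain(pulse_onsets_s=df["onset_s"].to_numpy(), pulse_duration_s=duration)


def read_waveforms(path) -> dict[str, dict[str, np.ndarray]]:
    """Load mean waveforms as {unit_id: {condition: voltage array}}."""
    df = pd.read_csv(path, dtype={"unit_id": str})
    for col in ("unit_id", "condition", "sample_index", "voltage_uv"):
        if col not in df.columns:
            raise FormatError(f"waveforms file {path} missing column {col!r}")
    out: dict[str, dict[str, np.ndarray]] = {}
    for (unit_id, cond), grp in df.groupby(["unit_id", "condition"], sort=True):
        if cond not in ("baseline", "evoked"):
            raise FormatError(f"waveforms file {path}: unknown condition {cond!r}")
        grp = grp.sort_values("sample_index")
        out.setdefault(str(unit_id), {})[str(cond)] = grp["voltage_uv"].to_numpy(dtype=float)
    return out


def attach_waveforms(trains: list[SpikeTrain], waveforms: dict[str, dict[str, np.ndarray]]) -> None:
    for train in trains:
        wf = waveforms.get(train.unit_id)
        if wf:
            train.mean_waveform_baseline = wf.get("baseline")
            train.mean_waveform_evoked = wf.get("evoked")


def session_firing_rate(spikes: SpikeTrain, first_laser_s: float) -> float:
    """Average rate over the behavioral session, up to the first laser pulse."""
    if not first_laser_s > 0:
        raise ValueError(f"first_laser_s must be positive, got {first_laser_s}")
    n = int(np.count_nonzero(spikes.spike_times_s < first_laser_s))
    return n / first_laser_s


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_run_metadata(path, config: SessionConfig, extra: dict | None = None) -> None:
    """YAML sidecar recording the config (and seed) that produced a run."""
    meta = {"config": config.to_dict()}
    if extra:
        meta.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
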