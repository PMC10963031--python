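"""Whole-body motion: speed, motion/walking bouts, start/stop events.

Body speed is the magnitude of the frame-to-frame derivative of the
average position of the six tracked body parts. Motion bouts are runs
where speed exceeds 50 mm/s for at least 0.3 s, extended backward and
forward to the surrounding 20 mm/s hysteresis crossings; bouts whose
extended boundaries touch are merged. Bouts are promoted from "motion"
to "walking" when most limbs show rhythmic 1-8 Hz motion, an automated
surrogate for manual acceptance of gait frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import SessionConfig
from .types import LIMBS, PoseTrack

__all__ = [
    "BodySpeedSeries",
    "MotionBout",
    "body_speed",
    "detect_motion_bouts",
    "classify_walking",
    "session_behavior_metrics",
    "movement_events",
]


@dataclass
class BodySpeedSeries:
    """Smoothed body speed with centroid path and unwrapped heading.

    ``speed_mm_s`` and ``heading_deg`` have length n_frames - 1 and are
    aligned to the interval following each frame; sample ``i`` is
    timestamped ``i / frame_rate``.
    """

    speed_mm_s: np.ndarray
    centroid_mm: np.ndarray
    heading_deg: np.ndarray
    frame_rate_hz: float
    valid: np.ndarray

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.speed_mm_s.size) / self.frame_rate_hz


@dataclass
class MotionBout:
    """One motion bout; times are hysteresis-extended boundaries."""

    start_s: float
    stop_s: float
    start_idx: int
    stop_idx: int  # inclusive speed-sample index
    kind: str = "motion"  # or "walking"
    heading_change_deg: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


def body_speed(pose: PoseTrack, config: SessionConfig) -> BodySpeedSeries:
    """Speed from the derivative of the six-part average position.

    The raw 80 Hz derivative chatters across thresholds, so speed is
    smoothed with a 0.25 s moving average before bout detection. Frames
    with tracking dropouts propagate as invalid samples with zero speed
    so they can never seed a bout.
    """
    if pose.n_frames < 2:
        raise ValueError("body_speed requires at least 2 frames")
    centroid = pose.centroid()
    vel = np.diff(centroid, axis=0) * config.frame_rate_hz
    speed = np.linalg.norm(vel, axis=1)
    valid = pose.valid[:-1] & pose.valid[1:]
    speed[~valid] = 0.0
    win = max(1, int(round(config.speed_smooth_s * config.frame_rate_hz)))
    vel_smooth = vel
    if win > 1:
        kernel = np.ones(win) / win
        speed = np.convolve(speed, kernel, mode="same")
        # heading needs the smoothed velocity *vector*: the raw per-frame
        # centroid velocity direction is dominated by limb-oscillation
        # residuals during walking
        vel_smooth = np.column_stack(
            [np.convolve(vel[:, 0], kernel, mode="same"), np.convolve(vel[:, 1], kernel, mode="same")]
        )
    heading = np.unwrap(np.arctan2(vel_smooth[:, 1], vel_smooth[:, 0]))
    return BodySpeedSeries(
        speed_mm_s=speed,
        centroid_mm=centroid,
        heading_deg=np.rad2deg(heading),
        frame_rate_hz=config.frame_rate_hz,
        valid=valid,
    )


def detect_motion_bouts(speed: BodySpeedSeries, config: SessionConfig) -> list[MotionBout]:
    """Threshold-plus-hysteresis bout detection.

    Contiguous runs with speed > ``speed_high_mm_s`` whose duration is
    at least ``min_bout_s`` are kept (the minimum applies to this
    suprathreshold core, before extension). Each is then extended
    backward/forward through all samples >= ``speed_low_mm_s``;
    overlapping or touching extended bouts are merged.
    """
    v = speed.speed_mm_s
    fs = speed.frame_rate_hz
    n = v.size
    high = v > config.speed_high_mm_s
    min_len = int(np.ceil(config.min_bout_s * fs))

    bouts: list[tuple[int, int]] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[False], high, [False]]).astype(int)))
    for run_start, run_end in zip(edges[::2], edges[1::2] - 1):
        if run_end - run_start + 1 < min_len:
            continue
        lo = run_start
        while lo > 0 and v[lo - 1] >= config.speed_low_mm_s:
            lo -= 1
        hi = run_end
        while hi < n - 1 and v[hi + 1] >= config.speed_low_mm_s:
            hi += 1
        if bouts and lo <= bouts[-1][1] + 1:
            bouts[-1] = (bouts[-1][0], max(bouts[-1][1], hi))
        else:
            bouts.append((lo, hi))

    out = []
    for lo, hi in bouts:
        heading_change = speed.heading_deg[hi] - speed.heading_deg[lo]
        if not getattr(config, "contraversive_ccw", True):
            heading_change = -heading_change
        out.append(
            MotionBout(
                start_s=lo / fs,
                stop_s=hi / fs,
                start_idx=lo,
                stop_idx=hi,
                heading_change_deg=float(heading_change),
            )
        )
    return out


def rhythmicity_index(projection: np.ndarray, frame_rate: float) -> float:
    """Fraction of spectral power in the 1-8 Hz gait band (vs 0-20 Hz)."""
    x = np.asarray(projection, dtype=float)
    x = x - x.mean()
    if x.size < 8 or not np.any(x):
        return 0.0
    freqs, pxx = signal.periodogram(x, fs=frame_rate)
    total = pxx[(freqs > 0) & (freqs <= 20.0)].sum()
    if total <= 0:
        return 0.0
    band = pxx[(freqs >= 1.0) & (freqs <= 8.0)].sum()
    return float(band / total)


def classify_walking(
    bouts: list[MotionBout],
    projections: dict[str, np.ndarray],
    config: SessionConfig,
) -> list[MotionBout]:
    """Label bouts as walking when limb motion is rhythmic.

    A bout is walking when at least ``walking_min_limbs`` limbs have a
    rhythmicity index >= the threshold. Bouts shorter than
    ``min_walking_bout_s`` stay "motion": too few gait cycles to judge.
    Modifies ``kind`` in place and returns the list.
    """
    for bout in bouts:
        bout.kind = "motion"
        if bout.duration_s < config.min_walking_bout_s:
            continue
        sl = slice(bout.start_idx, bout.stop_idx + 2)  # samples -> frames
        n_rhythmic = sum(
            rhythmicity_index(projections[limb][sl], config.frame_rate_hz)
            >= config.rhythmicity_threshold
            for limb in LIMBS
            if limb in projections
        )
        if n_rhythmic >= config.walking_min_limbs:
            bout.kind = "walking"
    return bouts


def session_behavior_metrics(
    bouts: list[MotionBout], speed: BodySpeedSeries
) -> dict[str, float]:
    """Session-level locomotor metrics.

    Mean body speed, total centroid path length, movement-initiation
    rate (bouts per minute), and the mean per-bout heading change
    (positive = contraversive by the configured convention).
    """
    duration_s = speed.speed_mm_s.size / speed.frame_rate_hz
    step = np.linalg.norm(np.diff(speed.centroid_mm, axis=0), axis=1)
    metrics = {
        "mean_speed_mm_s": float(speed.speed_mm_s.mean()),
        "total_distance_mm": float(step[speed.valid].sum()),
        "initiation_rate_per_min": 60.0 * len(bouts) / duration_s if duration_s else 0.0,
        "mean_heading_change_deg": (
            float(np.mean([b.heading_change_deg for b in bouts])) if bouts else 0.0
        ),
        "n_bouts": float(len(bouts)),
        "n_walking_bouts": float(sum(b.kind == "walking" for b in bouts)),
    }
    return metrics


def movement_events(
    bouts: list[MotionBout], session_duration_s: float, config: SessionConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Start/stop event times with peri-event eligibility flags.

    Events whose full peri-event span (baseline through post-event
    window) falls outside the session are flagged ineligible.
    """
    starts = np.array([b.start_s for b in bouts])
    stops = np.array([b.stop_s for b in bouts])
    lo, hi = config.peri_event_span_s
    start_ok = (starts + lo >= 0) & (starts + hi <= session_duration_s)
    stop_ok = (stops + lo >= 0) & (stops + hi <= session_duration_s)
    return starts, stops, start_ok, stop_ok
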