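"""Single-limb gait analysis: stride segmentation and limb phase.

Limb coordinates are smoothed (3rd-order Savitzky-Golay), projected onto
the nose-tail body axis, and band-pass filtered 0.5-8 Hz. In the
projection (positive toward the tail), the minimum marks the limb's
anterior extreme, the stance onset; the following maximum (posterior
extreme) marks the swing onset; the next minimum closes the stride.
Within each stride, limb phase runs linearly from 0 deg at stance onset
to 360 deg at the next stance onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .circstats import angular_deviation, mean_vector
from .config import SessionConfig
from .motion import MotionBout
from .types import LIMBS, PoseTrack

__all__ = [
    "Stride",
    "LimbPhaseSeries",
    "smooth_tracks",
    "project_limb",
    "bandpass_gait",
    "detect_strides",
    "limb_phase",
    "strides_to_frame",
    "gait_summary",
]


@dataclass
class Stride:
    """One stance -> swing -> stance cycle of a single limb."""

    limb: str
    stance_on_s: float
    swing_on_s: float
    next_stance_on_s: float
    length_mm: float
    bout_id: int = -1

    def __post_init__(self) -> None:
        if not self.stance_on_s < self.swing_on_s < self.next_stance_on_s:
            raise ValueError("stride events must be ordered stance < swing < next stance")

    @property
    def duration_s(self) -> float:
        return self.next_stance_on_s - self.stance_on_s

    @property
    def speed_mm_s(self) -> float:
        return self.length_mm / self.duration_s

    @property
    def swing_stance_ratio(self) -> float:
        return (self.next_stance_on_s - self.swing_on_s) / (self.swing_on_s - self.stance_on_s)


@dataclass
class LimbPhaseSeries:
    """Per-frame gait phase of one limb.

    ``phase_deg`` is in [0, 360) inside accepted strides and NaN
    elsewhere; ``stride_id`` indexes into the stride list (-1 outside).
    """

    limb: str
    phase_deg: np.ndarray
    stride_id: np.ndarray
    frame_rate_hz: float

    @property
    def valid(self) -> np.ndarray:
        return self.stride_id >= 0

    @property
    def n_valid_frames(self) -> int:
        return int(np.count_nonzero(self.valid))


def smooth_tracks(pose: PoseTrack, config: SessionConfig) -> PoseTrack:
    """Savitzky-Golay smoothing of every coordinate.

    Order 3 as standard; the 7-frame window (87.5 ms at 80 fps) keeps
    content up to the 8 Hz top of the gait band.
    """
    if pose.n_frames < config.savgol_window:
        raise ValueError(
            f"track of {pose.n_frames} frames shorter than the "
            f"{config.savgol_window}-frame smoothing window"
        )
    coords = {
        part: signal.savgol_filter(
            xy, config.savgol_window, config.savgol_order, axis=0, mode="interp"
        )
        for part, xy in pose.coords.items()
    }
    return PoseTrack(
        frame_index=pose.frame_index.copy(),
        coords=coords,
        frame_rate_hz=pose.frame_rate_hz,
        valid=pose.valid.copy(),
    )


def project_limb(pose: PoseTrack, limb: str) -> np.ndarray:
    """Project a limb onto the nose->tail axis, relative to the body.

    Returns dot(limb - body reference, unit(tail - nose)) per frame, so
    the projection grows toward the tail and its minimum is the limb's
    anterior extreme. The body reference is the nose-tail midpoint: a
    reference averaging the limbs themselves (the six-part centroid)
    would feed every limb's oscillation back into every projection and
    bias stance/swing onset timing. Frames with a degenerate
    (zero-length) axis come back NaN.
    """
    axis = pose.coords["tail"] - pose.coords["nose"]
    norm = np.linalg.norm(axis, axis=1)
    reference = 0.5 * (pose.coords["nose"] + pose.coords["tail"])
    rel = pose.coords[limb] - reference
    with np.errstate(invalid="ignore", divide="ignore"):
        proj = np.einsum("ij,ij->i", rel, axis) / norm
    proj[norm == 0] = np.nan
    return proj


def bandpass_gait(series: np.ndarray, frame_rate: float, config: SessionConfig | None = None) -> np.ndarray:
    """Zero-phase 0.5-8 Hz band-pass of a projection series.

    A 3rd-order Butterworth run forward-backward (filtfilt): stance and
    swing onsets are timing-critical, so the filter must not shift them.
    """
    config = config or SessionConfig()
    if frame_rate <= 2 * config.band_high_hz:
        raise ValueError("frame rate too low for the gait band")
    sos = signal.butter(
        3, [config.band_low_hz, config.band_high_hz], btype="bandpass", fs=frame_rate, output="sos"
    )
    x = np.asarray(series, dtype=float)
    filled = x.copy()
    bad = ~np.isfinite(filled)
    if bad.all():
        return np.full_like(x, np.nan)
    if bad.any():  # interpolate over dropouts so the IIR filter stays finite
        idx = np.arange(x.size)
        filled[bad] = np.interp(idx[bad], idx[~bad], filled[~bad])
    return signal.sosfiltfilt(sos, filled)


def _alternating_extrema(
    x: np.ndarray, lo: int, hi: int, config: SessionConfig, frame_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Strictly alternating minima/maxima of x[lo:hi+1] (global indices).

    Candidate extrema come from local peak detection with a minimum
    separation of half a period at the band's top frequency and a
    minimum prominence; when two same-kind extrema are adjacent the
    lower-prominence one is discarded.
    """
    seg = x[lo : hi + 1]
    distance = max(1, int(round(config.min_peak_separation_s * frame_rate)))
    kw = dict(distance=distance, prominence=config.min_peak_prominence_mm)
    maxima, props_max = signal.find_peaks(seg, **kw)
    minima, props_min = signal.find_peaks(-seg, **kw)
    events = [(i, +1, p) for i, p in zip(maxima, props_max["prominences"])]
    events += [(i, -1, p) for i, p in zip(minima, props_min["prominences"])]
    events.sort()
    kept: list[tuple[int, int, float]] = []
    for ev in events:
        if kept and kept[-1][1] == ev[1]:
            if ev[2] > kept[-1][2]:
                kept[-1] = ev
        else:
            kept.append(ev)
    mins = np.array([i + lo for i, kind, _ in kept if kind == -1], dtype=int)
    maxs = np.array([i + lo for i, kind, _ in kept if kind == +1], dtype=int)
    return mins, maxs


_CORNER_HALFWIN = 4  # frames each side of the candidate extremum
_CORNER_GRID = np.arange(-2.0, 2.001, 0.25)  # breakpoint offsets, frames


def _corner_residual_projectors() -> np.ndarray:
    """Residual projector I - X pinv(X) per candidate breakpoint.

    The corner model is two line segments meeting at the breakpoint b:
    basis {1, min(x - b, 0), max(x - b, 0)} on x = -W..W.
    """
    x = np.arange(-_CORNER_HALFWIN, _CORNER_HALFWIN + 1, dtype=float)
    mats = []
    for b in _CORNER_GRID:
        design = np.column_stack(
            [np.ones_like(x), np.minimum(x - b, 0.0), np.maximum(x - b, 0.0)]
        )
        mats.append(np.eye(x.size) - design @ np.linalg.pinv(design))
    return np.stack(mats)


_CORNER_PROJ = _corner_residual_projectors()


def _refine_extrema(proj: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-frame extremum times by a broken-stick least-squares fit.

    The projection around a stance or swing onset is a corner: two
    near-linear segments with different slopes. A symmetric smoother or
    a discrete argmin both displace the extremum of such an asymmetric
    corner toward its shallow side under noise, biasing the recovered
    swing:stance ratio; fitting the two-segment model and taking the
    breakpoint is robust to both. Returns float frame positions
    (unchanged where the window leaves the series or contains NaNs).
    """
    out = np.asarray(idx, dtype=float).copy()
    if idx.size == 0:
        return out
    w = _CORNER_HALFWIN
    fitable = (idx >= w) & (idx < proj.size - w)
    windows = np.stack([proj[i - w : i + w + 1] for i in idx[fitable]]) if fitable.any() else None
    if windows is None:
        return out
    finite = np.isfinite(windows).all(axis=1)
    if finite.any():
        y = windows[finite]
        # SSE per (event, breakpoint); residual projectors are precomputed
        res = np.einsum("bij,ej->ebi", _CORNER_PROJ, y)
        sse = np.sum(res**2, axis=2)
        best = _CORNER_GRID[np.argmin(sse, axis=1)]
        target = out[fitable]
        target[finite] += best
        out[fitable] = target
    return out


def detect_strides(
    filtered: np.ndarray,
    bouts: list[MotionBout],
    limb: str,
    config: SessionConfig,
    smoothed_pose: PoseTrack | None = None,
    raw_pose: PoseTrack | None = None,
) -> list[Stride]:
    """Segment strides of one limb within walking bouts.

    Minima (stance onsets) and maxima (swing onsets) of the band-passed
    projection must alternate; a minimum -> maximum -> minimum triple
    within one bout is a stride, kept when its duration falls in the
    band-implied bounds. With ``config.refine_corners`` the onset times
    are refined to sub-frame precision on the least-smoothed projection
    available (the raw track when given, else the smoothed one).
    Stride length is the Euclidean distance the limb travels between
    the two stance onsets, measured on the smoothed (not band-passed)
    2-D track, which still contains the translation the band-pass
    removes.
    """
    fs = config.frame_rate_hz
    refine_proj = None
    if config.refine_corners:
        if raw_pose is not None:
            refine_proj = project_limb(raw_pose, limb)
        elif smoothed_pose is not None:
            refine_proj = project_limb(smoothed_pose, limb)
    strides: list[Stride] = []
    for bout_id, bout in enumerate(bouts):
        if bout.kind != "walking":
            continue
        lo, hi = bout.start_idx, min(bout.stop_idx + 1, filtered.size - 1)
        if hi - lo < 4:
            continue
        mins_i, maxs_i = _alternating_extrema(filtered, lo, hi, config, fs)
        if refine_proj is not None:
            mins = _refine_extrema(refine_proj, mins_i)
            maxs = _refine_extrema(refine_proj, maxs_i)
            # refinement must not reorder the alternating sequence
            if np.any(np.diff(mins) <= 0):
                mins = mins_i.astype(float)
            if np.any(np.diff(maxs) <= 0):
                maxs = maxs_i.astype(float)
        else:
            mins, maxs = mins_i.astype(float), maxs_i.astype(float)
        if mins.size < 2:
            continue
        for m0, m1 in zip(mins[:-1], mins[1:]):
            between = maxs[(maxs > m0) & (maxs < m1)]
            if between.size != 1:
                continue  # alternation already enforced; guard bout edges
            duration = (m1 - m0) / fs
            if not (config.stride_min_s <= duration <= config.stride_max_s):
                continue
            if smoothed_pose is not None:
                xy = smoothed_pose.coords[limb]
                length = float(
                    np.linalg.norm(xy[int(round(m1))] - xy[int(round(m0))])
                )
            else:
                length = float("nan")
            strides.append(
                Stride(
                    limb=limb,
                    stance_on_s=m0 / fs,
                    swing_on_s=float(between[0]) / fs,
                    next_stance_on_s=m1 / fs,
                    length_mm=length,
                    bout_id=bout_id,
                )
            )
    return strides


def limb_phase(
    strides: list[Stride], n_frames: int, config: SessionConfig, limb: str | None = None
) -> LimbPhaseSeries:
    """Per-frame phase: 0 deg at stance onset, linear to 360 deg.

    Frames outside accepted strides are invalid (NaN phase, id -1).
    """
    fs = config.frame_rate_hz
    phase = np.full(n_frames, np.nan)
    stride_id = np.full(n_frames, -1, dtype=int)
    limb_name = limb
    for sid, stride in enumerate(strides):
        if limb_name is None:
            limb_name = stride.limb
        # frames with stance_on <= t < next_stance_on; a frame lying
        # exactly on the stance onset gets phase 0
        f0 = int(np.ceil(stride.stance_on_s * fs - 1e-9))
        f1 = int(np.ceil(stride.next_stance_on_s * fs - 1e-9))
        frames = np.arange(max(f0, 0), min(f1, n_frames))
        phase[frames] = 360.0 * (frames / fs - stride.stance_on_s) / stride.duration_s
        stride_id[frames] = sid
    return LimbPhaseSeries(
        limb=limb_name or "", phase_deg=phase, stride_id=stride_id, frame_rate_hz=fs
    )


def strides_to_frame(strides: list[Stride]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "limb": s.limb,
                "stance_on_s": s.stance_on_s,
                "swing_on_s": s.swing_on_s,
                "next_stance_on_s": s.next_stance_on_s,
                "length_mm": s.length_mm,
                "duration_s": s.duration_s,
                "speed_mm_s": s.speed_mm_s,
                "bout_id": s.bout_id,
            }
            for s in strides
        ],
        columns=[
            "limb",
            "stance_on_s",
            "swing_on_s",
            "next_stance_on_s",
            "length_mm",
            "duration_s",
            "speed_mm_s",
            "bout_id",
        ],
    )


def gait_summary(strides_by_limb: dict[str, list[Stride]]) -> dict:
    """Per-limb stride statistics and inter-limb coordination.

    For each limb: mean/SD of length, duration, frequency and speed,
    the mean swing:stance duration ratio, and CVs of length and speed.
    Inter-limb coordination is expressed relative to the LR (reference)
    limb: the circular mean +/- angular deviation of each limb's stance
    onset phase within the LR cycle, and the mean relative swing-onset
    time in seconds.
    """
    per_limb = {}
    for limb, strides in strides_by_limb.items():
        if not strides:
            per_limb[limb] = {"n_strides": 0, "testable": False}
            continue
        lengths = np.array([s.length_mm for s in strides])
        durations = np.array([s.duration_s for s in strides])
        speeds = np.array([s.speed_mm_s for s in strides])
        ratios = np.array([s.swing_stance_ratio for s in strides])
        per_limb[limb] = {
            "n_strides": len(strides),
            "testable": True,
            "length_mm_mean": float(lengths.mean()),
            "length_mm_sd": float(lengths.std(ddof=1)) if len(strides) > 1 else 0.0,
            "duration_s_mean": float(durations.mean()),
            "duration_s_sd": float(durations.std(ddof=1)) if len(strides) > 1 else 0.0,
            "frequency_hz_mean": float((1.0 / durations).mean()),
            "speed_mm_s_mean": float(speeds.mean()),
            "speed_mm_s_sd": float(speeds.std(ddof=1)) if len(strides) > 1 else 0.0,
            "swing_stance_ratio": float(ratios.mean()),
            "length_cv": float(lengths.std(ddof=1) / lengths.mean()) if len(strides) > 1 else 0.0,
            "speed_cv": float(speeds.std(ddof=1) / speeds.mean()) if len(strides) > 1 else 0.0,
        }

    offsets: dict[str, dict] = {}
    ref = strides_by_limb.get("lr", [])
    for limb in LIMBS:
        if limb == "lr" or not ref:
            continue
        others = strides_by_limb.get(limb, [])
        stance_times = np.array([s.stance_on_s for s in others])
        swing_times = np.array([s.swing_on_s for s in others])
        phase_offsets = []
        swing_offsets = []
        for s in ref:
            in_cycle = stance_times[(stance_times >= s.stance_on_s) & (stance_times < s.next_stance_on_s)]
            if in_cycle.size:
                phase_offsets.append(360.0 * (in_cycle[0] - s.stance_on_s) / s.duration_s)
            sw = swing_times[(swing_times >= s.stance_on_s) & (swing_times < s.next_stance_on_s)]
            if sw.size:
                swing_offsets.append(sw[0] - s.swing_on_s)
        if phase_offsets:
            mv = mean_vector(phase_offsets)
            offsets[limb] = {
                "phase_offset_deg": mv.angle_deg,
                "phase_offset_ang_dev_deg": angular_deviation(mv),
                "swing_onset_offset_s": float(np.mean(swing_offsets)) if swing_offsets else float("nan"),
                "n_cycles": len(phase_offsets),
            }
    return {"per_limb": per_limb, "relative_to_lr": offsets}
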