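"""Shared domain types for the gait/spiking pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BODY_PARTS",
    "LIMBS",
    "DIAGONAL_PAIRS",
    "FormatError",
    "IntegrityError",
    "PoseTrack",
    "SpikeTrain",
    "LaserPulseTrain",
]

#: tracked body parts: nose, tail base and the four limbs
#: (lf/lr/rf/rr = left-front, left-rear, right-front, right-rear)
BODY_PARTS = ("nose", "tail", "lf", "lr", "rf", "rr")
LIMBS = ("lf", "lr", "rf", "rr")
#: limb pairs that move in phase during lateral-sequence walking
DIAGONAL_PAIRS = (frozenset({"lf", "rr"}), frozenset({"rf", "lr"}))


class FormatError(ValueError):
    """Input file does not match the expected tabular schema."""


class IntegrityError(ValueError):
    """Input violates a structural invariant (e.g. frame gaps)."""


@dataclass
class PoseTrack:
    """Per-frame 2-D coordinates of the six tracked body parts, in mm.

    ``coords[part]`` is an (n_frames, 2) float array. Frames where any
    part was lost by the tracker are flagged in ``valid`` rather than
    carried as silent NaNs; invalid frames are excluded from bout and
    stride analysis downstream.
    """

    frame_index: np.ndarray
    coords: dict[str, np.ndarray]
    frame_rate_hz: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        n = self.frame_index.size
        if n == 0:
            raise IntegrityError("empty pose track")
        diffs = np.diff(self.frame_index)
        if np.any(diffs != 1):
            raise IntegrityError("frame_index must be gapless and strictly increasing")
        missing = [p for p in BODY_PARTS if p not in self.coords]
        if missing:
            raise FormatError(f"pose track missing body parts: {missing}")
        for part, xy in self.coords.items():
            xy = np.asarray(xy, dtype=float)
            if xy.shape != (n, 2):
                raise IntegrityError(f"{part} coordinates have shape {xy.shape}, expected {(n, 2)}")
            self.coords[part] = xy
        finite = np.ones(n, dtype=bool)
        for xy in self.coords.values():
            finite &= np.isfinite(xy).all(axis=1)
        if self.valid is None:
            self.valid = finite
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & finite

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.size)

    @property
    def time_s(self) -> np.ndarray:
        """Frame times; the camera is clocked at a fixed frame rate."""
        return self.frame_index / self.frame_rate_hz

    @property
    def dropout_fraction(self) -> float:
        return float(1.0 - self.valid.mean())

    def centroid(self) -> np.ndarray:
        """(n_frames, 2) mean position of the six tracked parts."""
        return np.mean([self.coords[p] for p in BODY_PARTS], axis=0)


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit, with optional mean waveforms.

    Waveforms (baseline vs laser-evoked, microvolts on a shared sample
    grid) are only needed for optogenetic tagging.
    """

    unit_id: str
    spike_times_s: np.ndarray
    mean_waveform_baseline: np.ndarray | None = None
    mean_waveform_evoked: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.size and t.min() < 0:
            raise ValueError(f"unit {self.unit_id}: negative spike time")
        self.spike_times_s = np.sort(t)
        wb, we = self.mean_waveform_baseline, self.mean_waveform_evoked
        if wb is not None:
            self.mean_waveform_baseline = np.asarray(wb, dtype=float)
        if we is not None:
            self.mean_waveform_evoked = np.asarray(we, dtype=float)
        if (
            self.mean_waveform_baseline is not None
            and self.mean_waveform_evoked is not None
            and self.mean_waveform_baseline.size != self.mean_waveform_evoked.size
        ):
            raise ValueError(f"unit {self.unit_id}: waveforms differ in length")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)


@dataclass
class LaserPulseTrain:
    """Onsets of the optogenetic-tagging laser pulses.

    The standard protocol delivers 200 pulses of 10 ms duration, one
    every 3 s, after the behavioral recording.
    """

    pulse_onsets_s: np.ndarray
    pulse_duration_s: float = 0.010

    def __post_init__(self) -> None:
        t = np.sort(np.asarray(self.pulse_onsets_s, dtype=float))
        if t.size > 1 and np.min(np.diff(t)) < self.pulse_duration_s:
            raise ValueError("inter-pulse interval shorter than pulse duration")
        self.pulse_onsets_s = t

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_onsets_s.size)
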