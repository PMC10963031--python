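"""Session-level analysis configuration.

Every fixed constant of the analysis lives here: acquisition calibration
(frame rate, mm per pixel), bout-detection thresholds, phase-histogram
binning, null-distribution sizes, peri-event windows, speed binning and
the optogenetic-tagging criteria. Downstream modules take a
:class:`SessionConfig` rather than loose keyword arguments so that a run
is fully described by one (config, seed) pair.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["SessionConfig"]


@dataclass
class SessionConfig:
    """Analysis constants for one recording session.

    Defaults reproduce the standard acquisition and analysis settings:
    80 fps bottom-up video at 0.3 mm/pixel, 50/20 mm/s bout hysteresis
    with a 0.3 s minimum, 15-degree phase bins, a +/-0.5 s spike-time
    jitter null with 100 iterations, a -5..-1 s baseline versus +/-0.5 s
    event window in 20 ms bins, 10 mm/s speed bins, and the three-part
    tagging criterion (6 ms latency, waveform r > 0.95, amplitude
    ratio < 2) with a 0.6 ms laser-artifact exclusion window.
    """

    frame_rate_hz: float = 80.0
    mm_per_pixel: float = 0.3

    # motion-bout detection
    speed_high_mm_s: float = 50.0
    speed_low_mm_s: float = 20.0
    min_bout_s: float = 0.3
    speed_smooth_s: float = 0.25
    #: walking requires >= this many limbs above the rhythmicity threshold
    walking_min_limbs: int = 3
    rhythmicity_threshold: float = 0.5
    min_walking_bout_s: float = 2.0
    #: positive heading change = contraversive; flip if the camera mirrors
    contraversive_ccw: bool = True

    # stride segmentation
    savgol_window: int = 7
    savgol_order: int = 3
    band_low_hz: float = 0.5
    band_high_hz: float = 8.0
    min_peak_separation_s: float = 0.0625
    min_peak_prominence_mm: float = 0.5
    stride_min_s: float = 0.125
    stride_max_s: float = 2.0
    #: refine band-passed extrema to sub-frame stance/swing onsets by a
    #: broken-stick fit to the unfiltered projection; the band-pass
    #: symmetrizes the stance/swing waveform and biases onset timing,
    #: which the unfiltered track retains
    refine_corners: bool = True

    # phase coding
    phase_bin_deg: float = 15.0
    jitter_halfwidth_s: float = 0.5
    n_jitter: int = 100
    min_spikes: int = 50
    min_strides: int = 30
    vector_length_outlier: float = 0.9

    # start/stop coding
    baseline_window_s: tuple[float, float] = (-5.0, -1.0)
    event_halfwidth_s: float = 0.5
    event_bin_s: float = 0.020
    peri_event_span_s: tuple[float, float] = (-5.0, 2.0)
    min_events: int = 5

    # speed coding
    speed_bin_mm_s: float = 10.0
    min_speed_occupancy_s: float = 1.0
    n_speed_shuffle: int = 100
    #: default significance uses the shuffle criterion; "pearson" selects
    #: the parametric correlation p instead
    speed_significance: str = "shuffle"

    # angular permutation test
    n_perm: int = 1000

    # optogenetic tagging
    tag_latency_max_s: float = 0.006
    tag_artifact_s: float = 0.0006
    tag_waveform_r_min: float = 0.95
    tag_amp_ratio_max: float = 2.0
    tag_test: str = "ttest"  # or "binomial" for very low rates

    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            ("frame_rate_hz", self.frame_rate_hz),
            ("mm_per_pixel", self.mm_per_pixel),
            ("speed_high_mm_s", self.speed_high_mm_s),
            ("speed_low_mm_s", self.speed_low_mm_s),
            ("min_bout_s", self.min_bout_s),
            ("phase_bin_deg", self.phase_bin_deg),
            ("jitter_halfwidth_s", self.jitter_halfwidth_s),
            ("n_jitter", self.n_jitter),
            ("n_perm", self.n_perm),
            ("event_halfwidth_s", self.event_halfwidth_s),
            ("event_bin_s", self.event_bin_s),
            ("speed_bin_mm_s", self.speed_bin_mm_s),
            ("tag_latency_max_s", self.tag_latency_max_s),
            ("tag_artifact_s", self.tag_artifact_s),
            ("tag_waveform_r_min", self.tag_waveform_r_min),
            ("tag_amp_ratio_max", self.tag_amp_ratio_max),
            ("vector_length_outlier", self.vector_length_outlier),
        ]
        for name, value in positive:
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not self.speed_low_mm_s < self.speed_high_mm_s:
            raise ValueError(
                "speed_low_mm_s must be below speed_high_mm_s "
                f"({self.speed_low_mm_s} >= {self.speed_high_mm_s})"
            )
        b0, b1 = self.baseline_window_s
        if not b0 < b1 <= -self.event_halfwidth_s:
            raise ValueError("baseline window must precede the event window")
        if 360.0 % self.phase_bin_deg != 0:
            raise ValueError("360 must be divisible by phase_bin_deg")
        if self.savgol_window <= self.savgol_order:
            raise ValueError("savgol_window must exceed savgol_order")

    @property
    def n_phase_bins(self) -> int:
        return int(round(360.0 / self.phase_bin_deg))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["baseline_window_s"] = list(self.baseline_window_s)
        d["peri_event_span_s"] = list(self.peri_event_span_s)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SessionConfig":
        d = dict(d)
        for key in ("baseline_window_s", "peri_event_span_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SessionConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
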