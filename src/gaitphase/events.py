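"""Start/stop coding and body-speed tuning.

Start/stop coding compares, per event, the mean firing rate in a
-5..-1 s baseline window against the mean rate within +/-0.5 s of the
event with a two-sided paired t-test. The modulation index normalizes
the cross-event mean PSTH by its baseline mean (so baseline ~ 1),
takes the maximum of the 20 ms-binned PSTH within +/-0.5 s of the
event, and reports |FR_event - FR_baseline| / FR_baseline.

Speed coding bins the full-session body speed in 10 mm/s steps,
computes mean firing rate per occupied bin, and scores the absolute
Pearson correlation of rate against bin speed; significance comes from
shuffling the rate values across bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import SessionConfig
from .motion import BodySpeedSeries

__all__ = [
    "PeriEventMatrix",
    "StartStopResult",
    "SpeedTuning",
    "peri_event_rates",
    "start_stop_test",
    "modulation_index",
    "speed_tuning",
    "speed_coding_score",
]


@dataclass
class PeriEventMatrix:
    """Events x time-bins firing rate around movement events."""

    rates_hz: np.ndarray  # (n_events, n_bins)
    bin_centers_s: np.ndarray
    event_times_s: np.ndarray
    bin_s: float

    @property
    def n_events(self) -> int:
        return int(self.rates_hz.shape[0])

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.bin_centers_s >= lo) & (self.bin_centers_s < hi)


@dataclass
class StartStopResult:
    start_p: float
    stop_p: float
    start_index: float
    stop_index: float
    start_testable: bool
    stop_testable: bool

    @property
    def coding(self) -> bool:
        """Significant modulation at either start or stop."""
        ps = [p for p, ok in ((self.start_p, self.start_testable), (self.stop_p, self.stop_testable)) if ok]
        return any(p < 0.05 for p in ps)


@dataclass
class SpeedTuning:
    bin_centers_mm_s: np.ndarray
    rate_hz: np.ndarray
    occupancy_s: np.ndarray
    testable: bool


def peri_event_rates(
    spike_times_s: np.ndarray, event_times_s: np.ndarray, config: SessionConfig
) -> PeriEventMatrix | None:
    """20 ms-binned firing rate around each eligible event.

    Span is the configured peri-event window (-5..+2 s by default).
    Returns None when there are no eligible events.
    """
    events = np.asarray(event_times_s, dtype=float)
    if events.size == 0:
        return None
    lo, hi = config.peri_event_span_s
    n_bins = int(round((hi - lo) / config.event_bin_s))
    edges = lo + np.arange(n_bins + 1) * config.event_bin_s
    t = np.asarray(spike_times_s, dtype=float)
    rates = np.empty((events.size, n_bins))
    for i, ev in enumerate(events):
        rel = t[(t >= ev + lo) & (t < ev + hi)] - ev
        rates[i] = np.histogram(rel, bins=edges)[0] / config.event_bin_s
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PeriEventMatrix(rates_hz=rates, bin_centers_s=centers, event_times_s=events, bin_s=config.event_bin_s)


def start_stop_test(matrix: PeriEventMatrix | None, config: SessionConfig) -> tuple[float, bool]:
    """Paired t-test of baseline vs event-window rate across events.

    Returns (two-sided p, testable). Untestable with fewer than
    ``min_events`` events or zero-variance paired differences.
    """
    if matrix is None or matrix.n_events < config.min_events:
        return float("nan"), False
    b0, b1 = config.baseline_window_s
    base = matrix.rates_hz[:, matrix.window_mask(b0, b1)].mean(axis=1)
    ev = matrix.rates_hz[:, matrix.window_mask(-config.event_halfwidth_s, config.event_halfwidth_s)].mean(axis=1)
    if np.allclose(base, ev):
        return float("nan"), False
    res = stats.ttest_rel(ev, base)
    return float(res.pvalue), True


def modulation_index(matrix: PeriEventMatrix | None, config: SessionConfig) -> tuple[float, bool]:
    """|FR_event - FR_baseline| / FR_baseline on the normalized mean PSTH.

    FR_event is the maximum of the cross-event mean PSTH within the
    +/-0.5 s event window (per-event maxima would inflate the index);
    after normalization FR_baseline is 1 by construction. Untestable
    when the baseline rate is zero.
    """
    if matrix is None or matrix.n_events == 0:
        return float("nan"), False
    psth = matrix.rates_hz.mean(axis=0)
    b0, b1 = config.baseline_window_s
    baseline = psth[matrix.window_mask(b0, b1)].mean()
    if baseline <= 0:
        return float("nan"), False
    norm = psth / baseline
    fr_event = norm[matrix.window_mask(-config.event_halfwidth_s, config.event_halfwidth_s)].max()
    return float(abs(fr_event - 1.0)), True


def speed_tuning(
    spike_times_s: np.ndarray, speed: BodySpeedSeries, config: SessionConfig
) -> SpeedTuning:
    """Mean firing rate per 10 mm/s body-speed bin over the session.

    Spikes are assigned to speed samples by flooring the spike time;
    bins occupied for less than the occupancy floor (1 s) are dropped.
    Untestable with fewer than 3 usable bins.
    """
    fs = speed.frame_rate_hz
    v = speed.speed_mm_s
    dt = 1.0 / fs
    sample_bins = (v // config.speed_bin_mm_s).astype(int)
    n_bins = int(sample_bins.max()) + 1 if v.size else 0
    occupancy = np.bincount(sample_bins, minlength=n_bins) * dt

    t = np.asarray(spike_times_s, dtype=float)
    frames = np.floor(t * fs).astype(np.int64)
    ok = (frames >= 0) & (frames < v.size)
    spike_counts = np.bincount(sample_bins[frames[ok]], minlength=n_bins).astype(float)

    keep = occupancy >= config.min_speed_occupancy_s
    centers = (np.arange(n_bins) + 0.5) * config.speed_bin_mm_s
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = spike_counts / occupancy
    return SpeedTuning(
        bin_centers_mm_s=centers[keep],
        rate_hz=rate[keep],
        occupancy_s=occupancy[keep],
        testable=bool(keep.sum() >= 3),
    )


def speed_coding_score(
    tuning: SpeedTuning,
    config: SessionConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, float, bool]:
    """Absolute Pearson r of rate vs speed, with a bin-shuffle null.

    Returns (r_abs, p_shuffle, p_pearson, testable). The shuffle
    permutes the rate values across speed bins 100 times; the add-one
    p counts shuffles whose |r| matches or exceeds the real one. Note
    the score is linear: U-shaped tuning yields low r_abs by design.
    """
    if not tuning.testable:
        return float("nan"), float("nan"), float("nan"), False
    x, y = tuning.bin_centers_mm_s, tuning.rate_hz
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return float("nan"), float("nan"), float("nan"), False
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    res = stats.pearsonr(x, y)
    r_abs = float(abs(res.statistic))
    n = config.n_speed_shuffle
    order = np.argsort(rng.random((n, y.size)), axis=1)
    shuffled = y[order]
    xc = x - x.mean()
    yc = shuffled - shuffled.mean(axis=1, keepdims=True)
    r_shuf = np.abs((yc @ xc) / (np.linalg.norm(xc) * np.linalg.norm(yc, axis=1)))
    p_shuffle = float((1 + np.count_nonzero(r_shuf >= r_abs)) / (1 + n))
    return r_abs, p_shuffle, float(res.pvalue), True
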