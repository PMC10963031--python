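"""Optogenetic tagging: classify units as light-identified cell types.

A unit is tagged when it satisfies all three criteria:

1. a significant excitatory response within 6 ms of laser onset
   (per-pulse spike counts in the response window versus a matched
   pre-pulse window, one-sided paired test);
2. Pearson r > 0.95 between the mean laser-evoked and mean baseline
   spike waveforms;
3. evoked/baseline trough-amplitude ratio < 2 (closing the scale-
   invariance loophole of the correlation).

Laser onset produces sub-millisecond photoelectric artifacts that can
masquerade as spikes, so spikes within 0.6 ms of any pulse onset are
removed first; genuine evoked responses start no earlier than 2 ms, so
the exclusion does not bite. The genotype behind a tagged unit (D1 vs
D2) comes from session metadata, not from the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import SessionConfig
from .types import LaserPulseTrain, SpikeTrain

__all__ = [
    "TaggingResult",
    "remove_artifact_spikes",
    "evoked_response_test",
    "waveform_criteria",
    "classify_tagged",
]


@dataclass
class TaggingResult:
    unit_id: str
    evoked_p: float
    latency_s: float
    waveform_r: float
    amp_ratio: float
    tagged: bool
    n_artifact_spikes_removed: int
    testable: bool


def remove_artifact_spikes(
    spike_times_s: np.ndarray, pulses: LaserPulseTrain, config: SessionConfig
) -> tuple[np.ndarray, int]:
    """Drop spikes within the artifact window [onset, onset + 0.6 ms)."""
    t = np.asarray(spike_times_s, dtype=float)
    onsets = pulses.pulse_onsets_s
    if onsets.size == 0 or t.size == 0:
        return t.copy(), 0
    idx = np.searchsorted(onsets, t, side="right") - 1
    has_prev = idx >= 0
    dt = np.where(has_prev, t - onsets[np.clip(idx, 0, None)], np.inf)
    artifact = has_prev & (dt >= 0) & (dt < config.tag_artifact_s)
    return t[~artifact], int(artifact.sum())


def _per_pulse_counts(
    t: np.ndarray, onsets: np.ndarray, lo: float, hi: float
) -> np.ndarray:
    """Spike counts in [onset + lo, onset + hi) per pulse."""
    return (
        np.searchsorted(t, onsets + hi) - np.searchsorted(t, onsets + lo)
    ).astype(float)


def evoked_response_test(
    spike_times_s: np.ndarray, pulses: LaserPulseTrain, config: SessionConfig
) -> tuple[float, float, bool]:
    """Test for short-latency excitatory responses to the laser.

    Per pulse, spikes in the response window (artifact end to 6 ms) are
    compared with a matched-duration window immediately before the
    pulse. Returns (one-sided p requiring excess spiking, median
    first-spike latency over responsive pulses, testable). Inhibited
    units are not significant by construction of the sidedness.
    """
    onsets = pulses.pulse_onsets_s
    if onsets.size < 50:
        raise ValueError(f"need >= 50 pulses for the evoked-response test, got {onsets.size}")
    t = np.asarray(spike_times_s, dtype=float)
    lo, hi = config.tag_artifact_s, config.tag_latency_max_s
    width = hi - lo
    resp = _per_pulse_counts(t, onsets, lo, hi)
    base = _per_pulse_counts(t, onsets, -width, 0.0)
    if resp.sum() == 0 and base.sum() == 0:
        return float("nan"), float("nan"), False

    if config.tag_test == "binomial":
        # sign test on pulses with unequal counts; exact, for very low rates
        greater = int(np.count_nonzero(resp > base))
        lesser = int(np.count_nonzero(resp < base))
        n = greater + lesser
        if n == 0:
            return 1.0, float("nan"), True
        p = float(stats.binomtest(greater, n, 0.5, alternative="greater").pvalue)
    else:
        diff = resp - base
        if np.allclose(diff, 0):
            return 1.0, float("nan"), True
        p = float(stats.ttest_rel(resp, base, alternative="greater").pvalue)

    latencies = []
    for onset in onsets:
        j = np.searchsorted(t, onset + lo)
        if j < t.size and t[j] < onset + hi:
            latencies.append(t[j] - onset)
    latency = float(np.median(latencies)) if latencies else float("nan")
    return p, latency, True


def waveform_criteria(unit: SpikeTrain) -> tuple[float, float, bool]:
    """Waveform similarity between baseline and laser-evoked spikes.

    Returns (Pearson r, |min(evoked)| / |min(baseline)| trough-amplitude
    ratio, testable). Untestable when either mean waveform is missing.
    """
    wb, we = unit.mean_waveform_baseline, unit.mean_waveform_evoked
    if wb is None or we is None:
        return float("nan"), float("nan"), False
    if wb.size != we.size:
        raise ValueError(f"unit {unit.unit_id}: waveform lengths differ")
    r = float(stats.pearsonr(wb, we).statistic)
    denom = abs(float(wb.min()))
    ratio = abs(float(we.min())) / denom if denom > 0 else float("inf")
    return r, ratio, True


def classify_tagged(
    unit: SpikeTrain, pulses: LaserPulseTrain, config: SessionConfig
) -> TaggingResult:
    """Apply artifact removal and the three tagging criteria to one unit."""
    cleaned, n_removed = remove_artifact_spikes(unit.spike_times_s, pulses, config)
    evoked_p, latency, resp_testable = evoked_response_test(cleaned, pulses, config)
    wf_r, amp_ratio, wf_testable = waveform_criteria(unit)
    testable = resp_testable and wf_testable
    tagged = bool(
        testable
        and evoked_p < 0.05
        and np.isfinite(latency)
        and latency <= config.tag_latency_max_s
        and wf_r > config.tag_waveform_r_min
        and amp_ratio < config.tag_amp_ratio_max
    )
    return TaggingResult(
        unit_id=unit.unit_id,
        evoked_p=evoked_p,
        latency_s=latency,
        waveform_r=wf_r,
        amp_ratio=amp_ratio,
        tagged=tagged,
        n_artifact_spikes_removed=n_removed,
        testable=testable,
    )
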