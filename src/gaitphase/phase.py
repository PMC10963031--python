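"""Spike / limb-phase coupling.

The firing rate as a function of limb phase is a 24-bin (15 deg)
histogram: spikes per phase bin divided by frames per phase bin, times
the frame rate. Spikes are assigned to frames by flooring the spike
time, and count only when that frame has a valid phase. Coupling
strength and preferred phase are the weighted circular mean vector of
this rate-versus-phase distribution — weighting by the occupancy-
corrected rate rather than using raw spike phases compensates for
non-uniform phase coverage.

Significance uses a spike-time jitter null: every spike is shifted by
an i.i.d. uniform(-0.5, +0.5) s offset and the vector length
recomputed, 100 times; the cell is phase-locked to a limb when its
real vector length exceeds more than 95% of the jittered ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circstats import MeanVector, mean_vector
from .config import SessionConfig
from .kinematics import LimbPhaseSeries
from .types import DIAGONAL_PAIRS, LIMBS

__all__ = [
    "PhaseHistogram",
    "JitterResult",
    "PhaseCodingResult",
    "phase_histogram",
    "phase_vector",
    "jitter_test",
    "classify_phase_locking",
]


@dataclass
class PhaseHistogram:
    """Occupancy-corrected firing rate versus limb phase."""

    bin_edges_deg: np.ndarray
    spike_counts: np.ndarray
    frame_counts: np.ndarray
    rate_hz: np.ndarray
    n_valid_spikes: int
    testable: bool

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])

    @property
    def empty_bins(self) -> np.ndarray:
        return self.frame_counts == 0


@dataclass
class JitterResult:
    p: float
    r_real: float
    r_jitter: np.ndarray
    testable: bool

    @property
    def significant(self) -> bool:
        """Real R exceeds more than 95% of jittered vector lengths."""
        return self.testable and self.p < 0.05


@dataclass
class PhaseCodingResult:
    """Per-unit phase-coding summary across the four limbs."""

    vectors: dict[str, MeanVector]
    p_jitter: dict[str, float]
    significant: dict[str, bool]
    phase_locked_any: bool
    preferred_limb: str | None
    n_limbs_locked: int
    diagonal_pair: bool
    excluded_outlier: bool
    testable: bool


def _spike_frames(spike_times_s: np.ndarray, n_frames: int, fs: float) -> np.ndarray:
    frames = np.floor(np.asarray(spike_times_s, dtype=float) * fs).astype(np.int64)
    return frames


def _binned_counts(
    spike_times_s: np.ndarray, phase: LimbPhaseSeries, config: SessionConfig
) -> tuple[np.ndarray, int]:
    fs = config.frame_rate_hz
    n_bins = config.n_phase_bins
    frames = _spike_frames(spike_times_s, phase.phase_deg.size, fs)
    ok = (frames >= 0) & (frames < phase.phase_deg.size)
    frames = frames[ok]
    valid = phase.valid[frames]
    frames = frames[valid]
    bins = np.minimum((phase.phase_deg[frames] // config.phase_bin_deg).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    return counts, frames.size


def phase_histogram(
    spike_times_s: np.ndarray, phase: LimbPhaseSeries, config: SessionConfig
) -> PhaseHistogram:
    """Rate-versus-phase histogram for one unit and limb."""
    n_bins = config.n_phase_bins
    edges = np.arange(n_bins + 1) * config.phase_bin_deg
    valid_phases = phase.phase_deg[phase.valid]
    frame_counts = np.bincount(
        np.minimum((valid_phases // config.phase_bin_deg).astype(int), n_bins - 1),
        minlength=n_bins,
    ).astype(float)
    spike_counts, n_valid = _binned_counts(spike_times_s, phase, config)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = spike_counts / frame_counts * config.frame_rate_hz
    rate[frame_counts == 0] = 0.0
    testable = bool(frame_counts.sum() > 0)
    return PhaseHistogram(
        bin_edges_deg=edges,
        spike_counts=spike_counts,
        frame_counts=frame_counts,
        rate_hz=rate,
        n_valid_spikes=n_valid,
        testable=testable,
    )


def phase_vector(hist: PhaseHistogram) -> MeanVector | None:
    """Mean vector of the rate-versus-phase distribution.

    Returns None (untestable) when every bin rate is zero.
    """
    if not hist.testable or not np.any(hist.rate_hz > 0):
        return None
    return mean_vector(hist.bin_centers_deg, weights=hist.rate_hz)


def _rates_to_r(spike_counts: np.ndarray, frame_counts: np.ndarray, unit_vectors: np.ndarray) -> np.ndarray:
    """Vector length from binned counts; supports (n_iter, n_bins) stacks."""
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = spike_counts / frame_counts
    rates = np.where(frame_counts > 0, rates, 0.0)
    total = rates.sum(axis=-1)
    z = (rates * unit_vectors).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(z) / total
    return np.where(total > 0, r, 0.0)


def jitter_test(
    spike_times_s: np.ndarray,
    phase: LimbPhaseSeries,
    config: SessionConfig,
    rng: np.random.Generator | int | None = None,
) -> JitterResult:
    """Spike-time jitter significance test for one unit and limb.

    Jitter is applied in time, so jittered spikes re-enter the full
    frame/phase assignment (some land outside strides and drop out,
    preserving slow-rate structure in the null). Frame counts are
    unchanged by spike jitter. Units with fewer than ``min_spikes``
    valid-phase spikes, or whose limb has fewer than ``min_strides``
    strides, are untestable.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    fs = config.frame_rate_hz
    n_bins = config.n_phase_bins
    n_frames = phase.phase_deg.size
    t = np.asarray(spike_times_s, dtype=float)

    n_strides = int(phase.stride_id.max()) + 1 if phase.stride_id.size else 0
    hist = phase_histogram(t, phase, config)
    centers = np.deg2rad(hist.bin_centers_deg)
    unit_vec = np.exp(1j * centers)
    if hist.n_valid_spikes < config.min_spikes or n_strides < config.min_strides:
        return JitterResult(p=float("nan"), r_real=float("nan"), r_jitter=np.array([]), testable=False)

    r_real = float(_rates_to_r(hist.spike_counts, hist.frame_counts, unit_vec))

    jit = t[None, :] + rng.uniform(-config.jitter_halfwidth_s, config.jitter_halfwidth_s, size=(config.n_jitter, t.size))
    frames = np.floor(jit * fs).astype(np.int64)
    inside = (frames >= 0) & (frames < n_frames)
    frames_clipped = np.clip(frames, 0, n_frames - 1)
    valid = phase.valid[frames_clipped] & inside
    phases = np.nan_to_num(phase.phase_deg[frames_clipped])  # invalid frames are masked below
    bins = np.minimum((phases // config.phase_bin_deg).astype(int), n_bins - 1)
    # one bincount over all iterations via a per-iteration offset
    offs = bins + np.arange(config.n_jitter)[:, None] * n_bins
    flat = offs[valid]
    counts = np.bincount(flat, minlength=config.n_jitter * n_bins).reshape(config.n_jitter, n_bins).astype(float)
    r_jit = _rates_to_r(counts, hist.frame_counts[None, :], unit_vec[None, :])
    p = float((1 + np.count_nonzero(r_jit >= r_real)) / (1 + config.n_jitter))
    return JitterResult(p=p, r_real=r_real, r_jitter=r_jit, testable=True)


def classify_phase_locking(
    per_limb: dict[str, tuple[MeanVector | None, JitterResult]],
    config: SessionConfig,
) -> PhaseCodingResult:
    """Combine the four per-limb tests into a unit-level classification.

    The outlier rule is applied first: units whose maximum vector
    length exceeds the 0.9 outlier threshold are excluded from all
    coding analyses. Otherwise the unit is phase-locked if any limb's
    jitter test is significant; when exactly two limbs are locked the
    diagonal-pair flag records whether they form a diagonal (LF+RR or
    RF+LR).
    """
    vectors: dict[str, MeanVector] = {}
    p_jitter: dict[str, float] = {}
    significant: dict[str, bool] = {}
    testable_any = False
    for limb in LIMBS:
        mv, jr = per_limb.get(limb, (None, None))
        if mv is not None:
            vectors[limb] = mv
        if jr is not None and jr.testable:
            testable_any = True
            p_jitter[limb] = jr.p
            significant[limb] = jr.significant
        else:
            p_jitter[limb] = float("nan")
            significant[limb] = False

    max_r = max((mv.length for mv in vectors.values()), default=0.0)
    excluded = max_r > config.vector_length_outlier
    if excluded:
        return PhaseCodingResult(
            vectors=vectors,
            p_jitter=p_jitter,
            significant={limb: False for limb in LIMBS},
            phase_locked_any=False,
            preferred_limb=None,
            n_limbs_locked=0,
            diagonal_pair=False,
            excluded_outlier=True,
            testable=testable_any,
        )

    locked = [limb for limb in LIMBS if significant.get(limb, False)]
    preferred = None
    if vectors:
        preferred = max(vectors, key=lambda limb: vectors[limb].length)
    diagonal = len(locked) == 2 and frozenset(locked) in DIAGONAL_PAIRS
    return PhaseCodingResult(
        vectors=vectors,
        p_jitter=p_jitter,
        significant=significant,
        phase_locked_any=bool(locked),
        preferred_limb=preferred,
        n_limbs_locked=len(locked),
        diagonal_pair=diagonal,
        excluded_outlier=False,
        testable=testable_any,
    )
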