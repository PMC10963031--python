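"""Synthetic walking-mouse sessions with known ground truth.

The generator emulates the statistical structure the analysis consumes,
not biomechanics: bout-structured open-field locomotion of a
lateral-sequence quadruped (in-phase diagonal limbs, anti-phase
ipsilateral front/rear pairs), with healthy and dopamine-lesion
kinematic regimes, plus spike trains whose rate is modulated by limb
phase (cosine tuning), body speed, start/stop transients, and
laser-evoked responses for optogenetic tagging.

Limb kinematics: a master gait oscillator advances at the stride
frequency; each limb's cycle is offset by its inter-limb phase lag.
Within a cycle the limb's position along the body axis is a
piecewise-linear sawtooth — posterior drift at the body speed during
stance, anterior return during swing — which makes the swing:stance
ratio an explicit parameter (a sinusoid could not), smoothed with a
3-frame moving average so extrema detection faces realistic waveforms.
The limb's anterior extreme (minimum of the nose->tail projection)
marks stance onset, matching the analyzer's convention.

Spike trains are inhomogeneous Poisson by thinning with

    r(t) = r0 * prod_limb(1 + m cos(phi(t) - phi0))
              * max(0.1, 1 + beta (v - vbar)/vbar)
              * (1 + gamma exp(-(t - t_start)^2 / 2 sigma^2))

(phase factor 1 outside walking, rate floored at 0.1 r0). For a single
modulated limb the asymptotic spike-phase mean vector length is m/2.
The rate model is a test harness, not a scientific claim about MSN
encoding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import SessionConfig
from .types import LIMBS, LaserPulseTrain, PoseTrack, SpikeTrain

__all__ = [
    "GaitParams",
    "NeuronModel",
    "TrueStride",
    "GroundTruth",
    "SessionData",
    "generate_gait",
    "generate_spikes",
    "generate_laser",
    "generate_cohort",
    "healthy_params",
    "lesion_params",
    "make_neuron",
]

_BODY_XY = {  # body frame, mm: x toward nose, y to the animal's left
    "nose": (45.0, 0.0),
    "tail": (-45.0, 0.0),
    "lf": (25.0, 15.0),
    "lr": (-25.0, 15.0),
    "rf": (25.0, -15.0),
    "rr": (-25.0, -15.0),
}


@dataclass
class GaitParams:
    """Kinematic regime of the simulated animal.

    Inter-limb stance-onset offsets are degrees of the master cycle
    relative to LR; the defaults realize the lateral-sequence footfall
    order LR -> LF -> RR -> RF with diagonal limbs near in-phase and
    ipsilateral front/rear pairs near anti-phase. Stride length follows
    speed through L = length_base / (1 - length_speed_coef * f), a
    mild positive length-speed relationship.
    """

    mean_stride_freq_hz: float = 3.0
    sd_stride_freq_hz: float = 0.3
    stride_length_base_mm: float = 45.0
    stride_length_speed_coef: float = 0.05
    limb_offsets_deg: dict[str, float] = field(
        default_factory=lambda: {"lr": 0.0, "lf": 170.0, "rr": 190.0, "rf": 350.0}
    )
    #: per-stride SD of each limb's stance-onset timing, in degrees of
    #: the cycle: stride-to-stride inter-limb variability, without
    #: which all four limbs are rigidly coupled and a neuron locked to
    #: one limb is exactly equally locked to all. Zero by default so
    #: the footfall sequence is strictly ordered for kinematic
    #: validation; the cohort presets enable it
    offset_jitter_deg: float = 0.0
    swing_fraction: float = 0.45
    bout_rate_per_min: float = 3.0
    bout_duration_mean_s: float = 8.0
    bout_duration_sd_s: float = 3.0
    turning_bias_deg_per_s: float = 0.0
    heading_noise_deg_per_sqrt_s: float = 8.0
    arena_mm: float = 600.0
    quiescent_speed_sd_mm_s: float = 3.0
    tracking_noise_mm: float = 0.3
    ramp_s: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.swing_fraction < 1.0:
            raise ValueError("swing_fraction must be in (0, 1)")
        for limb, off in self.limb_offsets_deg.items():
            if not 0.0 <= off < 360.0:
                raise ValueError(f"{limb} offset must be in [0, 360)")
        off = self.limb_offsets_deg

        def circ_dist(a: float, b: float) -> float:
            d = abs((a - b + 180.0) % 360.0 - 180.0)
            return d

        if circ_dist(off["lr"], off["rf"]) > 20 or circ_dist(off["lf"], off["rr"]) > 20:
            raise ValueError("diagonal limb pairs must be within 20 deg of in-phase")
        if (
            circ_dist(off["lf"] - off["lr"], 180.0) > 20
            or circ_dist(off["rf"] - off["rr"], 180.0) > 20
        ):
            raise ValueError("ipsilateral front/rear pairs must be within 20 deg of anti-phase")

    @property
    def nominal_speed_mm_s(self) -> float:
        f = self.mean_stride_freq_hz
        length = self.stride_length_base_mm / (1.0 - self.stride_length_speed_coef * f)
        return f * length


@dataclass
class NeuronModel:
    """Ground-truth rate model of one simulated unit."""

    unit_id: str
    r0_hz: float = 5.0
    mod_depth: dict[str, float] = field(default_factory=dict)  # limb -> m in [0, 1)
    preferred_phase_deg: dict[str, float] = field(default_factory=dict)
    speed_gain: float = 0.0  # beta
    start_gain: float = 0.0  # gamma
    start_sigma_s: float = 0.2
    stop_gain: float = 0.0
    tagged: bool = False
    cell_type: str = "untagged"  # d1 | d2 | untagged
    evoke_prob: float = 0.8
    evoke_latency_mean_s: float = 0.0035
    evoke_latency_sd_s: float = 0.001
    waveform_amp_uv: float = 100.0
    evoked_amp_factor: float = 1.1

    def __post_init__(self) -> None:
        for limb, m in self.mod_depth.items():
            if not 0.0 <= m < 1.0:
                raise ValueError(f"modulation depth for {limb} must be in [0, 1)")


@dataclass(frozen=True)
class TrueStride:
    stance_on_s: float
    swing_on_s: float
    next_stance_on_s: float


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    walking: np.ndarray  # per-frame bool
    speed_mm_s: np.ndarray  # per-frame programmed body speed
    phase_deg: dict[str, np.ndarray]  # per-frame true limb phase (NaN outside walking)
    bouts: list[tuple[float, float]]  # low-threshold (20 mm/s) crossings
    strides: dict[str, list[TrueStride]]
    params: GaitParams
    neurons: list[NeuronModel] = field(default_factory=list)

    @property
    def mean_walking_speed(self) -> float:
        w = self.walking
        return float(self.speed_mm_s[w].mean()) if w.any() else 0.0


@dataclass
class SessionData:
    """One complete simulated session ready for the pipeline."""

    pose: PoseTrack
    spikes: list[SpikeTrain]
    laser: LaserPulseTrain | None
    truth: GroundTruth
    cell_types: dict[str, str]
    regime: str = "healthy"

    @property
    def first_laser_s(self) -> float | None:
        if self.laser is None or self.laser.n_pulses == 0:
            return None
        return float(self.laser.pulse_onsets_s[0])


def _sawtooth(phase_deg: np.ndarray, swing_fraction: float) -> np.ndarray:
    """Unit-amplitude limb cycle: +0.5 at stance onset (anterior), -0.5
    at swing onset (posterior), linear in between."""
    s = 1.0 - swing_fraction  # stance share
    p = np.mod(phase_deg, 360.0) / 360.0
    stance = p < s
    out = np.empty_like(p)
    out[stance] = 0.5 - p[stance] / s
    out[~stance] = -0.5 + (p[~stance] - s) / (1.0 - s)
    return out


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    kernel = np.ones(win) / win
    return np.convolve(x, kernel, mode="same")


def _bout_schedule(
    params: GaitParams, duration_s: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Alternating quiescent/walking epochs: (plateau start, plateau end)."""
    mean_cycle = 60.0 / params.bout_rate_per_min
    mean_gap = max(1.0, mean_cycle - params.bout_duration_mean_s - 2 * params.ramp_s)
    bouts = []
    t = max(2.0, rng.exponential(mean_gap))
    while t < duration_s - 4.0:
        d = rng.normal(params.bout_duration_mean_s, params.bout_duration_sd_s)
        d = float(np.clip(d, 2.5, duration_s))
        end = min(t + d, duration_s - 1.0)
        if end - t >= 2.5:
            bouts.append((t, end))
        t = end + 2 * params.ramp_s + max(1.0, rng.exponential(mean_gap))
    return bouts


def generate_gait(
    params: GaitParams,
    duration_s: float,
    seed: int | np.random.Generator = 0,
    config: SessionConfig | None = None,
) -> tuple[PoseTrack, GroundTruth]:
    """Simulate a pose track with known strides, bouts and limb phases.

    Walking epochs have trapezoidal speed envelopes (linear ramps of
    ``ramp_s``); the ground-truth bout boundaries are the programmed
    20 mm/s crossings on those ramps. Ground-truth strides are the
    master-oscillator stance crossings whose full cycle lies inside the
    constant-speed plateau. Heading integrates the turning bias plus
    noise, with reflective steering toward the arena center near walls.
    """
    config = config or SessionConfig()
    if duration_s < 10:
        raise ValueError("duration_s must be at least 10 s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = config.frame_rate_hz
    n = int(round(duration_s * fs))
    dt = 1.0 / fs
    v_nom = params.nominal_speed_mm_s
    if v_nom * dt >= params.arena_mm:
        raise ValueError("infeasible gait parameters: per-frame displacement exceeds arena")

    t_frames = np.arange(n) * dt
    envelope = np.zeros(n)
    master_phase = np.full(n, np.nan)  # deg, unwrapped within each walking epoch
    walking = np.zeros(n, dtype=bool)
    freq = np.zeros(n)
    plateau = np.zeros(n, dtype=bool)

    schedule = _bout_schedule(params, duration_s, rng)
    kept_bouts: list[tuple[float, float, float, np.ndarray, int, int]] = []
    for start, end in schedule:
        r = params.ramp_s
        t0, t1 = start - r, end + r  # envelope foot points
        i0, i1 = max(0, int(np.ceil(t0 * fs))), min(n - 1, int(np.floor(t1 * fs)))
        if i1 <= i0:
            continue
        tt = t_frames[i0 : i1 + 1]
        env = np.clip(np.minimum((tt - t0) / r, (t1 - tt) / r), 0.0, 1.0)
        envelope[i0 : i1 + 1] = env
        walking[i0 : i1 + 1] = True
        plateau[i0 : i1 + 1] = (tt >= start) & (tt <= end)
        # per-stride frequency: piecewise-constant, resampled every cycle
        f_cap = 1.5 * params.mean_stride_freq_hz
        n_strides_max = int(np.ceil((t1 - t0) * f_cap)) + 3
        fks = np.clip(
            rng.normal(params.mean_stride_freq_hz, params.sd_stride_freq_hz, n_strides_max),
            0.5 * params.mean_stride_freq_hz,
            f_cap,
        )
        # integrate phase: frequency switches at each completed cycle
        phi = np.empty(tt.size)
        cur = 0.0
        k = 0
        for j in range(tt.size):
            phi[j] = cur
            cur += 360.0 * fks[min(k, fks.size - 1)] * dt
            k = int(cur // 360.0)
        master_phase[i0 : i1 + 1] = phi
        fk_idx = np.minimum((phi // 360.0).astype(int), fks.size - 1)
        freq[i0 : i1 + 1] = fks[fk_idx]
        kept_bouts.append((start, end, t0, fks, i0, i1))

    coef = params.stride_length_speed_coef
    with np.errstate(divide="ignore"):
        stride_len = np.where(
            freq > 0, params.stride_length_base_mm / (1.0 - coef * freq), 0.0
        )
    v_plateau = freq * stride_len
    speed = v_plateau * envelope

    # ground-truth bout boundaries: 20 mm/s crossings of the programmed speed
    bout_bounds: list[tuple[float, float]] = []
    for _, _, _, _, i0, i1 in kept_bouts:
        seg = speed[i0 : i1 + 1]
        above = np.flatnonzero(seg >= config.speed_low_mm_s)
        if above.size:
            bout_bounds.append(((i0 + above[0]) * dt, (i0 + above[-1]) * dt))

    # heading and centroid path
    heading = np.zeros(n)
    origin = np.zeros((n, 2))
    pos = np.array([params.arena_mm / 2, params.arena_mm / 2])
    theta = rng.uniform(0, 2 * np.pi)
    margin, steer_rate = 80.0, np.deg2rad(120.0)
    bias = np.deg2rad(params.turning_bias_deg_per_s)
    noise_sd = np.deg2rad(params.heading_noise_deg_per_sqrt_s) * np.sqrt(dt)
    for i in range(n):
        origin[i] = pos
        heading[i] = theta
        if walking[i]:
            theta += bias * dt + rng.normal(0.0, noise_sd)
            # reflective steering: turn toward the center near walls
            to_wall = np.array(
                [min(pos[0], params.arena_mm - pos[0]), min(pos[1], params.arena_mm - pos[1])]
            )
            if to_wall.min() < margin:
                center_dir = np.arctan2(
                    params.arena_mm / 2 - pos[1], params.arena_mm / 2 - pos[0]
                )
                delta = (center_dir - theta + np.pi) % (2 * np.pi) - np.pi
                # a biased (lesioned) animal circles along the wall in
                # its turning direction rather than taking the shortest
                # rotation back toward the center
                if bias != 0.0 and np.sign(delta) != np.sign(bias):
                    delta = delta - np.sign(delta) * 2 * np.pi
                step = np.clip(delta, -steer_rate * dt, steer_rate * dt)
                theta += step
            pos = pos + speed[i] * dt * np.array([np.cos(theta), np.sin(theta)])
        else:
            pos = pos + rng.normal(0.0, params.quiescent_speed_sd_mm_s * dt, 2)
        pos = np.clip(pos, 5.0, params.arena_mm - 5.0)

    # limb phases from per-stride stance-crossing times. Each limb's
    # crossings are the master oscillator's offset crossings perturbed
    # by per-stride timing jitter (stride-to-stride inter-limb
    # variability); the phase is piecewise-linear between crossings, so
    # the emitted waveform, the declared stride truth, and the phase
    # series driving spike generation are mutually consistent.
    phase_deg: dict[str, np.ndarray] = {limb: np.full(n, np.nan) for limb in LIMBS}
    strides: dict[str, list[TrueStride]] = {limb: [] for limb in LIMBS}
    s_frac = 1.0 - params.swing_fraction
    jitter_sd_s = (params.offset_jitter_deg / 360.0) / params.mean_stride_freq_hz
    for start, end, t0, fks, i0, i1 in kept_bouts:
        dt_total = end + params.ramp_s - t0
        for limb in LIMBS:
            c = np.array(
                _phase_crossing_times(t0, fks, params.limb_offsets_deg[limb], dt_total)
            )
            if c.size < 2:
                continue
            if jitter_sd_s > 0:
                c = np.sort(c + rng.normal(0.0, jitter_sd_s, c.size))
            knots_t = np.concatenate([[2 * c[0] - c[1]], c, [2 * c[-1] - c[-2]]])
            knots_p = 360.0 * np.arange(-1, c.size + 1)
            tt = t_frames[i0 : i1 + 1]
            phase_deg[limb][i0 : i1 + 1] = np.mod(np.interp(tt, knots_t, knots_p), 360.0)
            for c0, c1 in zip(c[:-1], c[1:]):
                if c0 >= start and c1 <= end:
                    strides[limb].append(TrueStride(c0, c0 + s_frac * (c1 - c0), c1))

    # body-frame limb oscillation
    osc: dict[str, np.ndarray] = {}
    amp = stride_len * (1.0 - params.swing_fraction) * envelope  # peak-to-peak, mm
    for limb in LIMBS:
        lp = phase_deg[limb]
        wave = np.zeros(n)
        w = walking & np.isfinite(lp)
        wave[w] = _sawtooth(lp[w], params.swing_fraction) * amp[w]
        # 3-frame moving average: rounds the sawtooth corners so extrema
        # detection faces realistic waveforms without displacing the
        # extrema (wider symmetric kernels shift the corner of an
        # asymmetric-duration cycle toward its shallow side, so the
        # emitted waveform would contradict the declared stride truth)
        osc[limb] = _moving_average(wave, 3)

    # assemble arena-frame coordinates
    cos_t, sin_t = np.cos(heading), np.sin(heading)
    coords: dict[str, np.ndarray] = {}
    for part, (bx, by) in _BODY_XY.items():
        x_body = np.full(n, bx)
        if part in LIMBS:
            x_body = x_body + osc[part]
        y_body = np.full(n, by)
        x = origin[:, 0] + cos_t * x_body - sin_t * y_body
        y = origin[:, 1] + sin_t * x_body + cos_t * y_body
        noise = rng.normal(0.0, params.tracking_noise_mm, (n, 2))
        coords[part] = np.column_stack([x, y]) + noise

    pose = PoseTrack(frame_index=np.arange(n), coords=coords, frame_rate_hz=fs)

    truth = GroundTruth(
        walking=walking,
        speed_mm_s=speed,
        phase_deg=phase_deg,
        bouts=bout_bounds,
        strides=strides,
        params=params,
    )
    return pose, truth


def _phase_crossing_times(
    t0: float, fks: np.ndarray, offset_deg: float, dt_total: float
) -> list[float]:
    """Times (s, absolute) when the limb phase crosses 0 mod 360.

    The master oscillator starts at 0 deg at ``t0`` and advances at the
    piecewise-constant per-stride frequencies ``fks``; the limb's phase
    lags the master by ``offset_deg``.
    """
    out = []
    target = offset_deg
    t, phase, k = t0, 0.0, 0
    while t - t0 < dt_total and k < fks.size:
        f = fks[k]
        next_cycle_end = (k + 1) * 360.0
        while target < next_cycle_end:
            if target >= phase:
                tc = t + (target - phase) / (360.0 * f)
                if tc - t0 <= dt_total:
                    out.append(tc)
            target += 360.0
        t += (next_cycle_end - phase) / (360.0 * f)
        phase = next_cycle_end
        k += 1
    return out


def truth_phase_series(truth: GroundTruth, limb: str, config: SessionConfig):
    """Limb-phase series built from the generator's own stride list.

    Useful for testing spike-phase estimators in isolation from stride
    segmentation.
    """
    from .kinematics import Stride, limb_phase

    strides = [
        Stride(
            limb=limb,
            stance_on_s=s.stance_on_s,
            swing_on_s=s.swing_on_s,
            next_stance_on_s=s.next_stance_on_s,
            length_mm=float("nan"),
        )
        for s in truth.strides[limb]
    ]
    return limb_phase(strides, truth.walking.size, config, limb)


def rate_series(
    model: NeuronModel, truth: GroundTruth, config: SessionConfig, total_s: float | None = None
) -> np.ndarray:
    """Ground-truth firing rate on the frame grid (Hz)."""
    n = truth.walking.size
    fs = config.frame_rate_hz
    t = np.arange(n) / fs
    rate = np.full(n, model.r0_hz)
    for limb, m in model.mod_depth.items():
        phi0 = model.preferred_phase_deg.get(limb, 0.0)
        factor = np.ones(n)
        w = truth.walking
        factor[w] = 1.0 + m * np.cos(np.deg2rad(truth.phase_deg[limb][w] - phi0))
        rate *= factor
    if model.speed_gain != 0.0:
        vbar = truth.mean_walking_speed
        if vbar > 0:
            rate *= np.maximum(0.1, 1.0 + model.speed_gain * (truth.speed_mm_s - vbar) / vbar)
    if model.start_gain != 0.0 or model.stop_gain != 0.0:
        for start, stop in truth.bouts:
            if model.start_gain:
                rate *= 1.0 + model.start_gain * np.exp(
                    -((t - start) ** 2) / (2 * model.start_sigma_s**2)
                )
            if model.stop_gain:
                rate *= 1.0 + model.stop_gain * np.exp(
                    -((t - stop) ** 2) / (2 * model.start_sigma_s**2)
                )
    rate = np.maximum(rate, 0.1 * model.r0_hz)
    if total_s is not None and total_s > n / fs:
        extra = int(round((total_s - n / fs) * fs))
        rate = np.concatenate([rate, np.full(extra, model.r0_hz)])
    return rate


def generate_spikes(
    model: NeuronModel,
    truth: GroundTruth,
    config: SessionConfig,
    seed: int | np.random.Generator = 0,
    total_s: float | None = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train by thinning.

    The rate is piecewise-constant on the frame grid (so the analyzer's
    floor-to-frame spike assignment sees exactly the programmed phase).
    ``total_s`` extends the train past the behavioral epoch at the
    baseline rate (for the tagging protocol).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = config.frame_rate_hz
    rate = rate_series(model, truth, config, total_s=total_s)
    duration = rate.size / fs
    r_env = float(rate.max())
    if r_env <= 0:
        return SpikeTrain(unit_id=model.unit_id, spike_times_s=np.array([]))
    n_cand = rng.poisson(r_env * duration)
    t_cand = np.sort(rng.uniform(0.0, duration, n_cand))
    frames = np.minimum((t_cand * fs).astype(np.int64), rate.size - 1)
    accept = rng.random(n_cand) < rate[frames] / r_env
    return SpikeTrain(unit_id=model.unit_id, spike_times_s=t_cand[accept])


def _waveform_template(rng: np.random.Generator, amp_uv: float, n_samples: int = 32) -> np.ndarray:
    """Biphasic extracellular spike: sharp trough, slow repolarization."""
    i = np.arange(n_samples)
    trough = rng.uniform(7, 10)
    width = rng.uniform(1.5, 2.5)
    hump = trough + rng.uniform(5, 8)
    return -amp_uv * np.exp(-((i - trough) ** 2) / (2 * width**2)) + 0.35 * amp_uv * np.exp(
        -((i - hump) ** 2) / (2 * (2.2 * width) ** 2)
    )


def generate_laser(
    models: list[NeuronModel],
    trains: list[SpikeTrain],
    protocol: LaserPulseTrain,
    config: SessionConfig,
    seed: int | np.random.Generator = 0,
    per_spike_waveform_noise_uv: float = 40.0,
) -> None:
    """Add laser-evoked spikes and mean waveforms, in place.

    Tagged units gain at most one extra spike per pulse with probability
    ``evoke_prob``, at a latency drawn from a normal truncated to
    [2, 6] ms (evoked responses never precede 2 ms). The evoked mean
    waveform is the unit's template scaled by ``evoked_amp_factor``
    plus noise whose SD shrinks as 1/sqrt(n) with the number n of
    spikes falling in the laser response window — a mean waveform
    estimated from a handful of chance spikes is noisy, which is what
    distinguishes untagged units' evoked waveforms in practice.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onsets = protocol.pulse_onsets_s
    lo, hi = 0.002, config.tag_latency_max_s
    by_id = {m.unit_id: m for m in models}
    for train in trains:
        model = by_id[train.unit_id]
        t = train.spike_times_s
        if model.tagged and onsets.size:
            evoke = rng.random(onsets.size) < model.evoke_prob
            lat = rng.normal(model.evoke_latency_mean_s, model.evoke_latency_sd_s, onsets.size)
            # truncate by resampling out-of-range draws
            bad = (lat < lo) | (lat > hi)
            while bad.any():
                lat[bad] = rng.normal(model.evoke_latency_mean_s, model.evoke_latency_sd_s, bad.sum())
                bad = (lat < lo) | (lat > hi)
            t = np.sort(np.concatenate([t, (onsets + lat)[evoke]]))
            train.spike_times_s = t

        template = _waveform_template(rng, model.waveform_amp_uv)
        n_total = max(1, t.size)
        train.mean_waveform_baseline = template + rng.normal(
            0.0, per_spike_waveform_noise_uv / np.sqrt(n_total), template.size
        )
        in_window = _count_in_windows(t, onsets, config.tag_artifact_s, hi)
        n_evoked = max(1, in_window)
        evoked_template = template * (model.evoked_amp_factor if model.tagged else 1.0)
        train.mean_waveform_evoked = evoked_template + rng.normal(
            0.0, per_spike_waveform_noise_uv / np.sqrt(n_evoked), template.size
        )


def _count_in_windows(t: np.ndarray, onsets: np.ndarray, lo: float, hi: float) -> int:
    if onsets.size == 0 or t.size == 0:
        return 0
    return int((np.searchsorted(t, onsets + hi) - np.searchsorted(t, onsets + lo)).sum())


def healthy_params() -> GaitParams:
    return GaitParams(offset_jitter_deg=20.0)


def lesion_params() -> GaitParams:
    """6OHDA kinematic preset: slower, shorter, flatter-footed strides,
    higher stride variability, ipsiversive turning, fewer bouts."""
    return GaitParams(
        offset_jitter_deg=20.0,
        mean_stride_freq_hz=2.0,
        sd_stride_freq_hz=0.35,
        stride_length_base_mm=30.0,
        swing_fraction=0.35,
        bout_rate_per_min=1.5,
        bout_duration_mean_s=6.0,
        bout_duration_sd_s=2.5,
        turning_bias_deg_per_s=-15.0,
    )


_REGIME_PARAMS = {
    "healthy": healthy_params,
    "sham": healthy_params,
    "6ohda": lesion_params,
}


def make_neuron(
    unit_id: str,
    rng: np.random.Generator,
    cell_type: str = "untagged",
    regime: str = "healthy",
    modulated: bool = True,
) -> NeuronModel:
    """Draw one unit from the regime's population model.

    Healthy/sham: D1 and D2 modulation depths come from the same
    distribution (balanced phase-locking by construction) and D1 units
    carry a stronger start transient. 6OHDA: D2 depths are shifted up
    and the D1 start gain is reduced, realizing stronger D2
    phase-locking and a lost D1 start bias.
    """
    lesioned = regime == "6ohda"
    m_mean = 0.35
    if lesioned and cell_type == "d2":
        m_mean = 0.50
    start_gain = 1.5 if cell_type == "d1" else 0.8
    if lesioned and cell_type == "d1":
        start_gain = 0.8
    mod: dict[str, float] = {}
    phi: dict[str, float] = {}
    if modulated:
        limb = str(rng.choice(LIMBS))
        mod[limb] = float(np.clip(rng.normal(m_mean, 0.05), 0.05, 0.9))
        phi[limb] = float(rng.uniform(0, 360))
    return NeuronModel(
        unit_id=unit_id,
        r0_hz=float(rng.uniform(3.0, 8.0)),
        mod_depth=mod,
        preferred_phase_deg=phi,
        speed_gain=float(rng.uniform(0.3, 0.8)),
        start_gain=start_gain,
        stop_gain=float(rng.uniform(0.2, 0.6)),
        tagged=cell_type in ("d1", "d2"),
        cell_type=cell_type,
        waveform_amp_uv=float(rng.uniform(80, 150)),
    )


def generate_cohort(
    regime: str,
    n_mice: int,
    n_units: int,
    seed: int | np.random.Generator = 0,
    duration_s: float = 360.0,
    config: SessionConfig | None = None,
    with_laser: bool = True,
) -> list[SessionData]:
    """Simulate a cohort of sessions (one per mouse) for a regime.

    Units cycle through d1 / d2 / untagged cell types; the tagging
    protocol (200 pulses, one per 3 s) is appended 10 s after the
    behavioral epoch.
    """
    if regime not in _REGIME_PARAMS:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(_REGIME_PARAMS)}")
    config = config or SessionConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sessions = []
    for _ in range(n_mice):
        params = _REGIME_PARAMS[regime]()
        pose, truth = generate_gait(params, duration_s, rng, config)
        first_laser = duration_s + 10.0
        laser = None
        total_s = duration_s
        if with_laser:
            laser = LaserPulseTrain(pulse_onsets_s=first_laser + 3.0 * np.arange(200))
            total_s = first_laser + 3.0 * 200
        models, trains = [], []
        cell_types = {}
        kinds = ["d1", "d2", "untagged"]
        for u in range(n_units):
            cell_type = kinds[u % 3]
            model = make_neuron(f"u{u:03d}", rng, cell_type=cell_type, regime=regime)
            models.append(model)
            cell_types[model.unit_id] = cell_type
            trains.append(generate_spikes(model, truth, config, rng, total_s=total_s))
        if laser is not None:
            generate_laser(models, trains, laser, config, rng)
        truth.neurons = models
        sessions.append(
            SessionData(
                pose=pose,
                spikes=trains,
                laser=laser,
                truth=truth,
                cell_types=cell_types,
                regime=regime,
            )
        )
    return sessions
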