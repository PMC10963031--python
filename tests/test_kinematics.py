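"""Stride segmentation, limb projection, and gait summary."""

import numpy as np
import pytest

from gaitphase import SessionConfig
from gaitphase import kinematics as kin
from gaitphase.motion import MotionBout
from gaitphase.types import BODY_PARTS, PoseTrack


def make_pose(n, limb_x=None, fs=80.0):
    """Straight-walking pose with an optional LR limb x-trajectory."""
    coords = {}
    for part in BODY_PARTS:
        x = np.zeros(n)
        if part == "nose":
            x = x + 45.0
        elif part == "tail":
            x = x - 45.0
        coords[part] = np.column_stack([x, np.full(n, {"lf": 15.0, "lr": 15.0}.get(part, -15.0) if part in ("lf", "lr", "rf", "rr") else 0.0)])
    if limb_x is not None:
        coords["lr"] = np.column_stack([limb_x, np.full(n, 15.0)])
    return PoseTrack(frame_index=np.arange(n), coords=coords, frame_rate_hz=fs)


class TestSmoothTracks:
    def test_cubic_polynomial_reproduced_exactly(self, config):
        n = 50
        t = np.arange(n, dtype=float)
        cubic = 0.01 * t**3 - 0.3 * t**2 + t
        pose = make_pose(n, limb_x=cubic)
        out = kin.smooth_tracks(pose, config)
        # an order-3 filter passes cubics untouched (interior points)
        np.testing.assert_allclose(out.coords["lr"][3:-3, 0], cubic[3:-3], atol=1e-8)

    def test_constant_track_unchanged(self, config):
        pose = make_pose(20)
        out = kin.smooth_tracks(pose, config)
        np.testing.assert_allclose(out.coords["rf"], pose.coords["rf"], atol=1e-10)

    def test_impulse_noise_attenuated(self, config):
        n = 60
        line = np.linspace(0, 10, n)
        noisy = line.copy()
        noisy[30] += 5.0
        pose = make_pose(n, limb_x=noisy)
        out = kin.smooth_tracks(pose, config)
        resid_out = np.abs(out.coords["lr"][:, 0] - line).max()
        assert resid_out < 5.0 * 0.8

    def test_short_track_rejected(self, config):
        with pytest.raises(ValueError, match="shorter"):
            kin.smooth_tracks(make_pose(5), config)


class TestProjectLimb:
    def test_limb_at_nose_projects_anterior_of_limb_at_tail(self):
        pose = make_pose(3)
        at_nose = pose.coords["nose"].copy()
        at_tail = pose.coords["tail"].copy()
        pose.coords["lr"] = at_nose
        p_nose = kin.project_limb(pose, "lr").copy()
        pose.coords["lr"] = at_tail
        p_tail = kin.project_limb(pose, "lr")
        assert np.all(p_nose < p_tail)

    def test_rotation_invariance(self):
        pose = make_pose(4)
        base = kin.project_limb(pose, "lf")
        theta = np.deg2rad(90.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = PoseTrack(
            frame_index=pose.frame_index.copy(),
            coords={p: xy @ rot.T for p, xy in pose.coords.items()},
            frame_rate_hz=pose.frame_rate_hz,
        )
        np.testing.assert_allclose(kin.project_limb(rotated, "lf"), base, atol=1e-9)

    def test_perpendicular_displacement_invisible(self):
        pose = make_pose(3)
        base = kin.project_limb(pose, "rr").copy()
        pose.coords["rr"][:, 1] += 7.5  # purely lateral = orthogonal to axis
        np.testing.assert_allclose(kin.project_limb(pose, "rr"), base, atol=1e-9)

    def test_degenerate_axis_flagged_nan(self):
        pose = make_pose(3)
        pose.coords["tail"] = pose.coords["nose"].copy()
        assert np.isnan(kin.project_limb(pose, "lf")).all()


class TestBandpass:
    def test_dc_rejected(self, config):
        out = kin.bandpass_gait(np.full(800, 5.0), 80.0, config)
        assert np.abs(out).max() < 1e-6

    def test_gait_band_frequency_preserved(self, config):
        t = np.arange(1600) / 80.0
        x = np.sin(2 * np.pi * 3.0 * t)
        out = kin.bandpass_gait(x, 80.0, config)
        assert np.abs(out[200:-200]).max() == pytest.approx(1.0, rel=0.05)

    def test_high_frequency_attenuated(self, config):
        t = np.arange(1600) / 80.0
        x = np.sin(2 * np.pi * 20.0 * t)
        out = kin.bandpass_gait(x, 80.0, config)
        assert np.abs(out[200:-200]).max() < 0.1

    def test_low_frame_rate_rejected(self, config):
        with pytest.raises(ValueError, match="frame rate"):
            kin.bandpass_gait(np.zeros(100), 10.0, config)


class TestDetectStrides:
    def _strides_for(self, limb_x, config, n=None, kind="walking"):
        n = n or len(limb_x)
        pose = make_pose(n, limb_x=limb_x)
        filtered = kin.bandpass_gait(kin.project_limb(pose, "lr"), 80.0, config)
        bouts = [MotionBout(0.0, (n - 1) / 80.0, 0, n - 1, kind=kind)]
        return kin.detect_strides(filtered, bouts, "lr", config, smoothed_pose=pose)

    def test_two_hz_cycle_yields_expected_strides(self, config):
        """A 2 Hz limb cycle in a 10 s bout: 19-20 strides of ~0.5 s."""
        t = np.arange(800) / 80.0
        limb_x = 15.0 * np.cos(2 * np.pi * 2.0 * t)  # max (anterior) at t=0
        strides = self._strides_for(limb_x, config)
        assert 19 <= len(strides) <= 20
        # first/last stride abut the filter's boundary transient
        durations = [s.duration_s for s in strides[1:-1]]
        assert np.allclose(durations, 0.5, atol=0.02)

    def test_monotone_drift_yields_none(self, config):
        strides = self._strides_for(np.linspace(0, 100, 800), config)
        assert strides == []

    def test_non_walking_bout_skipped(self, config):
        t = np.arange(800) / 80.0
        strides = self._strides_for(15 * np.cos(2 * np.pi * 2 * t), config, kind="motion")
        assert strides == []

    def test_stride_duration_bounds_enforced(self, config):
        t = np.arange(800) / 80.0
        slow = 15.0 * np.cos(2 * np.pi * 0.4 * t)  # 2.5 s period > 2 s bound
        assert self._strides_for(slow, config) == []

    def test_two_close_minima_collapse_to_one_candidate(self, config):
        """Two minima closer than the half-period separation keep only
        the deeper one, so no spurious short stride arises between them."""
        i = np.arange(400, dtype=float)
        x = np.zeros(400)
        x -= 8.0 * np.exp(-((i - 100) ** 2) / 4.0)
        x -= 5.0 * np.exp(-((i - 104) ** 2) / 4.0)  # 4 frames away: < 5-frame rule
        mins, _ = kin._alternating_extrema(x, 0, 399, config, 80.0)
        assert mins.size == 1 and mins[0] == 100

    def test_kept_extrema_strictly_alternate(self, config):
        """After cleanup, minima and maxima alternate strictly, so every
        consecutive minimum pair brackets exactly one maximum."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = np.cumsum(rng.normal(0, 1.5, 600))
            mins, maxs = kin._alternating_extrema(x, 0, 599, config, 80.0)
            events = sorted([(m, -1) for m in mins] + [(m, +1) for m in maxs])
            kinds = [k for _, k in events]
            assert all(a != b for a, b in zip(kinds[:-1], kinds[1:]))
            for m0, m1 in zip(mins[:-1], mins[1:]):
                assert np.count_nonzero((maxs > m0) & (maxs < m1)) == 1


class TestLimbPhase:
    def make_strides(self):
        return [
            kin.Stride("lr", stance_on_s=1.0, swing_on_s=1.275, next_stance_on_s=1.5, length_mm=50.0),
            kin.Stride("lr", stance_on_s=1.5, swing_on_s=1.775, next_stance_on_s=2.0, length_mm=50.0),
        ]

    def test_phase_zero_at_stance_onset_frame(self, config):
        phase = kin.limb_phase(self.make_strides(), 200, config, "lr")
        assert phase.phase_deg[80] == pytest.approx(0.0)

    def test_phase_linear_midpoint(self, config):
        phase = kin.limb_phase(self.make_strides(), 200, config, "lr")
        assert phase.phase_deg[100] == pytest.approx(180.0)

    def test_frames_outside_strides_invalid(self, config):
        phase = kin.limb_phase(self.make_strides(), 200, config, "lr")
        assert not phase.valid[40] and np.isnan(phase.phase_deg[40])
        assert phase.stride_id[40] == -1

    def test_phase_strictly_increasing_within_stride(self, config):
        phase = kin.limb_phase(self.make_strides(), 200, config, "lr")
        seg = phase.phase_deg[80:120]
        assert np.all(np.diff(seg) > 0)


class TestGaitSummary:
    def test_identical_strides_have_zero_cv(self, config):
        strides = [
            kin.Stride("lr", t, t + 0.275, t + 0.5, length_mm=50.0) for t in np.arange(0, 5, 0.5)
        ]
        out = kin.gait_summary({"lr": strides})
        stats = out["per_limb"]["lr"]
        assert stats["length_cv"] == 0.0 and stats["speed_cv"] == 0.0
        assert stats["swing_stance_ratio"] == pytest.approx(0.225 / 0.275)

    def test_no_strides_marked_untestable(self):
        out = kin.gait_summary({"lr": []})
        assert out["per_limb"]["lr"]["testable"] is False

    def test_interlimb_offsets_recovered(self, config):
        """Offsets relative to LR: LF at 170 deg, RF at 350 deg."""
        lr = [kin.Stride("lr", t, t + 0.275, t + 0.5, 50.0) for t in np.arange(0, 6, 0.5)]
        lf = [kin.Stride("lf", t + 0.5 * 170 / 360, t + 0.51 * 170 / 360 + 0.275, t + 0.5 * 170 / 360 + 0.5, 50.0) for t in np.arange(0, 6, 0.5)]
        rf = [kin.Stride("rf", t + 0.5 * 350 / 360, t + 0.5 * 350 / 360 + 0.275, t + 0.5 * 350 / 360 + 0.5, 50.0) for t in np.arange(0, 6, 0.5)]
        out = kin.gait_summary({"lr": lr, "lf": lf, "rf": rf})
        assert out["relative_to_lr"]["lf"]["phase_offset_deg"] == pytest.approx(170.0, abs=2.0)
        assert out["relative_to_lr"]["rf"]["phase_offset_deg"] == pytest.approx(350.0, abs=2.0)
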