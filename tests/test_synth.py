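"""Ground-truth properties of the synthetic session generator."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from gaitphase import SessionConfig
from gaitphase import synth
from gaitphase.types import LIMBS, LaserPulseTrain, PoseTrack


class TestGenerateGait:
    def test_stride_count_matches_stride_frequency(self, config):
        """10 s of constant 3 Hz walking contains 30 +/- 1 strides/limb."""
        params = synth.GaitParams(
            sd_stride_freq_hz=0.0,
            bout_rate_per_min=0.8,
            bout_duration_mean_s=60.0,
            bout_duration_sd_s=0.0,
        )
        _, truth = synth.generate_gait(params, 90.0, seed=2, config=config)
        start, _ = truth.bouts[0]
        for limb in LIMBS:
            onsets = np.array([s.stance_on_s for s in truth.strides[limb]])
            n = np.count_nonzero((onsets >= start + 1) & (onsets < start + 11))
            assert abs(n - 30) <= 1

    def test_true_swing_stance_ratio_is_analytic(self, default_gait_session):
        """swing_fraction 0.45 fixes the ratio at 0.45/0.55 exactly."""
        _, truth = default_gait_session
        for limb in LIMBS:
            ratios = [
                (s.next_stance_on_s - s.swing_on_s) / (s.swing_on_s - s.stance_on_s)
                for s in truth.strides[limb]
            ]
            assert np.allclose(ratios, 0.45 / 0.55)

    def test_lateral_sequence_order_in_truth(self, default_gait_session):
        """Default offsets produce the LR -> LF -> RR -> RF footfall order."""
        _, truth = default_gait_session
        sw = {limb: np.array([s.swing_on_s for s in truth.strides[limb]]) for limb in LIMBS}
        checked = 0
        for a, b in zip(np.sort(sw["lr"])[:-1], np.sort(sw["lr"])[1:]):
            inside = [sw[l][(sw[l] > a) & (sw[l] <= b)] for l in ("lf", "rr", "rf")]
            if all(x.size == 1 for x in inside):
                assert inside[0][0] < inside[1][0] < inside[2][0]
                checked += 1
        assert checked > 50

    def test_zero_turning_bias_is_symmetric(self, config):
        """Without a turning bias, per-bout heading change averages to ~0."""
        params = synth.GaitParams(arena_mm=3000.0)  # large arena: few wall turns
        from gaitphase import motion as mo

        heads = []
        for seed in range(4):
            pose, _ = synth.generate_gait(params, 240.0, seed=seed, config=config)
            speed = mo.body_speed(pose, config)
            heads.extend(b.heading_change_deg for b in mo.detect_motion_bouts(speed, config))
        assert abs(np.mean(heads)) < 30.0

    def test_emitted_pose_satisfies_track_invariants(self, default_gait_session, config):
        pose, truth = default_gait_session
        assert isinstance(pose, PoseTrack)
        assert np.all(np.diff(pose.frame_index) == 1)
        assert pose.valid.all()
        for part in pose.coords.values():
            assert np.isfinite(part).all()
            assert part.min() >= 0 - 60 and part.max() <= truth.params.arena_mm + 60

    def test_short_duration_rejected(self, config):
        with pytest.raises(ValueError, match="at least 10"):
            synth.generate_gait(synth.GaitParams(), 5.0, config=config)

    def test_truth_phase_zero_at_stance_onset(self, default_gait_session, config):
        _, truth = default_gait_session
        phase = truth.phase_deg["lr"]
        for s in truth.strides["lr"][:50]:
            f = int(np.ceil(s.stance_on_s * config.frame_rate_hz))
            expected = (
                360.0
                * (f / config.frame_rate_hz - s.stance_on_s)
                / (s.next_stance_on_s - s.stance_on_s)
            )
            assert phase[f] == pytest.approx(expected, abs=1.0)


class TestGenerateSpikes:
    def test_thinning_reproduces_mean_rate(self, walking_truth, config):
        """Empirical count is within 3 SE of the integrated rate."""
        _, truth = walking_truth
        for m, beta in ((0.0, 0.0), (0.5, 0.6)):
            model = synth.NeuronModel(
                unit_id="u", r0_hz=8.0, mod_depth={"lr": m}, preferred_phase_deg={"lr": 40.0},
                speed_gain=beta,
            )
            rate = synth.rate_series(model, truth, config)
            expected = rate.sum() / config.frame_rate_hz
            train = synth.generate_spikes(model, truth, config, seed=9)
            assert abs(train.n_spikes - expected) < 3 * np.sqrt(expected)

    def test_single_limb_vector_length_is_half_m(self, walking_truth, walking_phase_lr, config):
        from gaitphase import phase as ph

        _, truth = walking_truth
        model = synth.NeuronModel(
            unit_id="u", r0_hz=40.0, mod_depth={"lr": 0.3}, preferred_phase_deg={"lr": 120.0}
        )
        train = synth.generate_spikes(model, truth, config, seed=10)
        hist = ph.phase_histogram(train.spike_times_s, walking_phase_lr, config)
        vec = ph.phase_vector(hist)
        assert hist.n_valid_spikes > 10_000
        assert vec.length == pytest.approx(0.15, abs=0.01)

    def test_unmodulated_unit_has_vanishing_vector(self, walking_truth, walking_phase_lr, config):
        from gaitphase import phase as ph

        _, truth = walking_truth
        model = synth.NeuronModel(unit_id="u", r0_hz=40.0)
        train = synth.generate_spikes(model, truth, config, seed=11)
        hist = ph.phase_histogram(train.spike_times_s, walking_phase_lr, config)
        assert ph.phase_vector(hist).length < 0.02

    def test_start_transient_peaks_near_three_baselines(self, walking_truth, config):
        """gamma=2 multiplies the rate by ~3 at bout starts."""
        _, truth = walking_truth
        model = synth.NeuronModel(unit_id="u", r0_hz=10.0, start_gain=2.0, start_sigma_s=0.2)
        rate = synth.rate_series(model, truth, config)
        starts = [int(b[0] * config.frame_rate_hz) for b in truth.bouts]
        assert np.mean([rate[s] for s in starts]) == pytest.approx(30.0, rel=0.05)


@pytest.fixture(scope="module")
def protocol():
    return LaserPulseTrain(pulse_onsets_s=1000.0 + 3.0 * np.arange(200))


class TestGenerateLaser:
    def test_evoked_spike_count_is_binomial(self, walking_truth, config, protocol):
        _, truth = walking_truth
        model = synth.NeuronModel(unit_id="u", r0_hz=0.1, tagged=True, evoke_prob=0.8)
        train = synth.generate_spikes(model, truth, config, seed=1, total_s=1620.0)
        before = train.n_spikes
        synth.generate_laser([model], [train], protocol, config, seed=2)
        gained = train.n_spikes - before
        assert abs(gained - 160) < 3 * np.sqrt(200 * 0.8 * 0.2) + 1

    def test_evoked_latencies_bounded(self, walking_truth, config, protocol):
        _, truth = walking_truth
        model = synth.NeuronModel(unit_id="u", r0_hz=0.0001, tagged=True)
        train = synth.generate_spikes(model, truth, config, seed=3, total_s=1620.0)
        synth.generate_laser([model], [train], protocol, config, seed=4)
        t = train.spike_times_s
        lat = t[:, None] - protocol.pulse_onsets_s[None, :]
        lat = lat[(lat > 0) & (lat < 0.1)]
        assert lat.size > 100
        assert lat.min() >= 0.002 and lat.max() <= 0.006

    def test_untagged_unit_gains_no_locked_spikes(self, walking_truth, config, protocol):
        _, truth = walking_truth
        model = synth.NeuronModel(unit_id="u", r0_hz=5.0, tagged=False)
        train = synth.generate_spikes(model, truth, config, seed=5, total_s=1620.0)
        before = train.n_spikes
        synth.generate_laser([model], [train], protocol, config, seed=6)
        assert train.n_spikes == before

    def test_matched_waveforms_correlate(self, walking_truth, config, protocol):
        _, truth = walking_truth
        model = synth.NeuronModel(unit_id="u", r0_hz=5.0, tagged=True, evoked_amp_factor=1.0)
        train = synth.generate_spikes(model, truth, config, seed=7, total_s=1620.0)
        synth.generate_laser([model], [train], protocol, config, seed=8)
        r = stats.pearsonr(train.mean_waveform_baseline, train.mean_waveform_evoked).statistic
        assert r > 0.99


class TestGenerateCohort:
    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError, match="unknown regime"):
            synth.generate_cohort("mystery", 1, 1)

    def test_behavior_only_session(self, config):
        sessions = synth.generate_cohort(
            "healthy", 1, 0, seed=1, duration_s=60.0, config=config, with_laser=False
        )
        assert sessions[0].spikes == [] and sessions[0].laser is None

    def test_healthy_modulation_balanced_lesion_biased(self):
        rng = np.random.default_rng(0)
        depths = {("healthy", "d1"): [], ("healthy", "d2"): [], ("6ohda", "d1"): [], ("6ohda", "d2"): []}
        for regime in ("healthy", "6ohda"):
            for ct in ("d1", "d2"):
                for i in range(200):
                    m = synth.make_neuron(f"u{i}", rng, cell_type=ct, regime=regime)
                    depths[(regime, ct)].extend(m.mod_depth.values())
        healthy_gap = np.mean(depths[("healthy", "d2")]) - np.mean(depths[("healthy", "d1")])
        lesion_gap = np.mean(depths[("6ohda", "d2")]) - np.mean(depths[("6ohda", "d1")])
        assert abs(healthy_gap) < 0.02
        assert lesion_gap > 0.1

    def test_lesion_preset_shifts_kinematics(self):
        h, l = synth.healthy_params(), synth.lesion_params()
        assert l.mean_stride_freq_hz < h.mean_stride_freq_hz
        assert l.swing_fraction < h.swing_fraction
        assert l.nominal_speed_mm_s < h.nominal_speed_mm_s
        assert l.turning_bias_deg_per_s < 0 and l.bout_rate_per_min < h.bout_rate_per_min


class TestGaitParamsValidation:
    def test_diagonal_pair_constraint(self):
        with pytest.raises(ValueError, match="diagonal"):
            synth.GaitParams(limb_offsets_deg={"lr": 0.0, "lf": 170.0, "rr": 190.0, "rf": 300.0})

    def test_swing_fraction_bounds(self):
        with pytest.raises(ValueError, match="swing_fraction"):
            synth.GaitParams(swing_fraction=1.2)
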