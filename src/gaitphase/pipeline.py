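"""Session-level orchestration: from raw tables to cell metrics.

``analyze_session`` runs the full chain — body speed, motion/walking
bouts, stride segmentation, limb phase, per-unit phase/start-stop/speed
coding and optogenetic tagging — and returns the three output tables
(cell_metrics, strides, bouts) plus session-level summaries.
``run_pipeline`` is the file-based wrapper used by the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import io as gio
from . import kinematics as kin
from . import motion as mo
from . import phase as ph
from . import tagging as tg
from .config import SessionConfig
from .types import LIMBS, LaserPulseTrain, PoseTrack, SpikeTrain

__all__ = ["SessionResult", "analyze_session", "run_pipeline"]

log = logging.getLogger("gaitphase")


@dataclass
class SessionResult:
    cell_metrics: pd.DataFrame
    strides: pd.DataFrame
    bouts: pd.DataFrame
    gait: dict
    behavior: dict
    phase_results: dict[str, ph.PhaseCodingResult] = field(default_factory=dict)
    strides_by_limb: dict[str, list[kin.Stride]] = field(default_factory=dict)
    phases_by_limb: dict[str, kin.LimbPhaseSeries] = field(default_factory=dict)
    speed: mo.BodySpeedSeries | None = None

    def summary(self) -> dict:
        """Headline session numbers."""
        cm = self.cell_metrics
        out = dict(self.behavior)
        out["n_units"] = len(cm)
        if len(cm):
            analyzed = cm[~cm["excluded_outlier"]]
            out["n_excluded_outlier"] = int(cm["excluded_outlier"].sum())
            out["frac_phase_locked"] = float(analyzed["phase_locked_any"].mean()) if len(analyzed) else float("nan")
            out["frac_start_stop"] = float(analyzed["start_stop_coding"].mean()) if len(analyzed) else float("nan")
            out["frac_speed"] = float(analyzed["speed_coding"].mean()) if len(analyzed) else float("nan")
            out["n_tagged"] = int(cm["tagged"].sum())
            r = analyzed[["session_rate_hz", "max_vector_length"]].dropna()
            if len(r) > 2 and r["max_vector_length"].std() > 0:
                out["rate_vs_vector_length_r"] = float(
                    np.corrcoef(r["session_rate_hz"], r["max_vector_length"])[0, 1]
                )
        for limb, stats in self.gait["per_limb"].items():
            if stats.get("testable"):
                out[f"{limb}_n_strides"] = stats["n_strides"]
        return out


def analyze_session(
    pose: PoseTrack,
    spikes: list[SpikeTrain],
    config: SessionConfig,
    laser: LaserPulseTrain | None = None,
) -> SessionResult:
    """Run every analysis stage on one session.

    Deterministic given ``config.rng_seed``: each (unit, analysis)
    pair draws from its own seed substream, so results do not depend
    on unit order. Sessions with zero walking bouts still produce
    event and speed metrics; phase columns are NaN/untestable.
    """
    first_laser = float(laser.pulse_onsets_s[0]) if laser is not None and laser.n_pulses else None
    behavior_end_s = first_laser if first_laser is not None else pose.n_frames / config.frame_rate_hz

    log.info("pose: %d frames, dropout %.3f", pose.n_frames, pose.dropout_fraction)
    speed = mo.body_speed(pose, config)
    bouts = mo.detect_motion_bouts(speed, config)
    smoothed = kin.smooth_tracks(pose, config)
    projections = {limb: kin.project_limb(smoothed, limb) for limb in LIMBS}
    filtered = {
        limb: kin.bandpass_gait(proj, config.frame_rate_hz, config)
        for limb, proj in projections.items()
    }
    mo.classify_walking(bouts, projections, config)
    log.info("bouts: %d total, %d walking", len(bouts), sum(b.kind == "walking" for b in bouts))

    strides_by_limb = {
        limb: kin.detect_strides(filtered[limb], bouts, limb, config, smoothed, raw_pose=pose)
        for limb in LIMBS
    }
    phases = {
        limb: kin.limb_phase(strides_by_limb[limb], pose.n_frames, config, limb)
        for limb in LIMBS
    }
    gait = kin.gait_summary(strides_by_limb)
    behavior = mo.session_behavior_metrics(bouts, speed)
    log.info("strides: %s", {limb: len(s) for limb, s in strides_by_limb.items()})

    starts, stops, start_ok, stop_ok = mo.movement_events(bouts, behavior_end_s, config)

    rows = []
    phase_results = {}
    root_ss = np.random.SeedSequence(config.rng_seed)
    for u, unit in enumerate(spikes):
        row: dict = {"unit_id": unit.unit_id}
        behav_spikes = unit.spike_times_s[unit.spike_times_s < behavior_end_s]
        row["session_rate_hz"] = (
            gio.session_firing_rate(unit, first_laser)
            if first_laser is not None
            else behav_spikes.size / behavior_end_s
        )

        # phase coding, one jitter substream per (unit, limb)
        per_limb = {}
        for li, limb in enumerate(LIMBS):
            hist = ph.phase_histogram(behav_spikes, phases[limb], config)
            vec = ph.phase_vector(hist)
            rng = np.random.default_rng(np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(u, li)))
            jr = ph.jitter_test(behav_spikes, phases[limb], config, rng)
            per_limb[limb] = (vec, jr)
            row[f"{limb}_vector_length"] = vec.length if vec else float("nan")
            row[f"{limb}_vector_angle_deg"] = vec.angle_deg if vec else float("nan")
            row[f"{limb}_phase_p"] = jr.p
        res = ph.classify_phase_locking(per_limb, config)
        phase_results[unit.unit_id] = res
        row["phase_locked_any"] = res.phase_locked_any
        row["preferred_limb"] = res.preferred_limb
        row["n_limbs_locked"] = res.n_limbs_locked
        row["diagonal_pair"] = res.diagonal_pair
        row["excluded_outlier"] = res.excluded_outlier
        row["max_vector_length"] = max((v.length for v in res.vectors.values()), default=float("nan"))

        # start/stop coding
        start_mat = ev.peri_event_rates(behav_spikes, starts[start_ok], config)
        stop_mat = ev.peri_event_rates(behav_spikes, stops[stop_ok], config)
        row["start_p"], start_testable = ev.start_stop_test(start_mat, config)
        row["stop_p"], stop_testable = ev.start_stop_test(stop_mat, config)
        row["start_index"], _ = ev.modulation_index(start_mat, config)
        row["stop_index"], _ = ev.modulation_index(stop_mat, config)
        ssr = ev.StartStopResult(
            start_p=row["start_p"],
            stop_p=row["stop_p"],
            start_index=row["start_index"],
            stop_index=row["stop_index"],
            start_testable=start_testable,
            stop_testable=stop_testable,
        )
        row["start_stop_coding"] = ssr.coding

        # speed coding
        tuning = ev.speed_tuning(behav_spikes, speed, config)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(u, 99)))
        r_abs, p_shuf, p_pearson, sp_testable = ev.speed_coding_score(tuning, config, rng)
        row["speed_r_abs"] = r_abs
        row["speed_p"] = p_shuf
        row["speed_p_pearson"] = p_pearson
        if not sp_testable:
            row["speed_coding"] = False
        elif config.speed_significance == "pearson":
            row["speed_coding"] = p_pearson < 0.05
        else:
            row["speed_coding"] = p_shuf < 0.05

        # optogenetic tagging
        if laser is not None and laser.n_pulses >= 50:
            tr = tg.classify_tagged(unit, laser, config)
            row["tagged"] = tr.tagged
            row["tag_latency_s"] = tr.latency_s
            row["tag_evoked_p"] = tr.evoked_p
            row["tag_waveform_r"] = tr.waveform_r
            row["tag_amp_ratio"] = tr.amp_ratio
        else:
            row["tagged"] = False
            row["tag_latency_s"] = float("nan")
            row["tag_evoked_p"] = float("nan")
            row["tag_waveform_r"] = float("nan")
            row["tag_amp_ratio"] = float("nan")
        rows.append(row)

    cell_metrics = pd.DataFrame(rows)
    all_strides = [s for limb in LIMBS for s in strides_by_limb[limb]]
    strides_df = kin.strides_to_frame(all_strides)
    bouts_df = pd.DataFrame(
        [
            {
                "bout_id": i,
                "start_s": b.start_s,
                "stop_s": b.stop_s,
                "kind": b.kind,
                "heading_change_deg": b.heading_change_deg,
            }
            for i, b in enumerate(bouts)
        ],
        columns=["bout_id", "start_s", "stop_s", "kind", "heading_change_deg"],
    )
    return SessionResult(
        cell_metrics=cell_metrics,
        strides=strides_df,
        bouts=bouts_df,
        gait=gait,
        behavior=behavior,
        phase_results=phase_results,
        strides_by_limb=strides_by_limb,
        phases_by_limb=phases,
        speed=speed,
    )


def run_pipeline(config: SessionConfig, paths: dict[str, str], out_dir: str) -> SessionResult:
    """File-based pipeline: read the session tables, analyze, write outputs.

    ``paths`` maps {pose, spikes, laser?, waveforms?} to CSV files.
    Writes cell_metrics.csv, strides.csv, bouts.csv and a YAML run
    sidecar into ``out_dir``. Deterministic given ``config.rng_seed``.
    """
    stage = "read inputs"
    try:
        pose = gio.read_pose(paths["pose"], config)
        spikes = gio.read_spikes(paths["spikes"])
        laser = gio.read_laser(paths["laser"]) if paths.get("laser") else None
        if paths.get("waveforms"):
            gio.attach_waveforms(spikes, gio.read_waveforms(paths["waveforms"]))
        stage = "analysis"
        result = analyze_session(pose, spikes, config, laser=laser)
        stage = "write outputs"
        out = Path(out_dir)
        gio.write_table(result.cell_metrics, out / "cell_metrics.csv")
        gio.write_table(result.strides, out / "strides.csv")
        gio.write_table(result.bouts, out / "bouts.csv")
        gio.write_run_metadata(
            out / "run.yaml",
            config,
            extra={"inputs": {k: str(v) for k, v in paths.items()}, "summary": _plain(result.summary())},
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc
    return result


def _plain(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out
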