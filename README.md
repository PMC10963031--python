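# gaitphase

Analysis pipeline linking dorsal-striatal single-unit spiking to
single-limb gait in freely walking mice, with a synthetic-session
generator that provides ground truth for every stage.

High-speed (80 fps) bottom-up video with markerless pose tracking gives
the 2-D positions of six body parts (nose, tail base, four limbs).
From these, the pipeline segments walking into strides, assigns each
video frame a *limb phase* (0° at stance onset, linear to 360° at the
next stance onset), and asks whether a neuron's spikes concentrate at a
particular phase of a limb's gait cycle — alongside the more
conventional whole-body measures: movement initiation/cessation and
body-speed coding. Units are classified as D1 or D2 medium spiny
neurons by optogenetic tagging.

## What it computes

**Gait kinematics.** Limb coordinates are smoothed (3rd-order
Savitzky–Golay), projected onto the nose–tail axis, and band-pass
filtered 0.5–8 Hz. Projection minima are stance onsets (limb closest to
the nose), maxima are swing onsets; a minimum→maximum→minimum triple is
one stride. Onset times are refined to sub-frame precision with a
broken-stick fit to the unfiltered projection. Motion bouts are runs of
body speed > 50 mm/s lasting ≥ 0.3 s, extended to the surrounding
20 mm/s hysteresis crossings; bouts with rhythmic 1–8 Hz limb motion
are promoted to walking bouts.

**Phase coding.** The firing rate versus limb phase is a 24-bin (15°)
histogram, occupancy-corrected: rate per bin = (spikes per bin / frames
per bin) × frame rate. Coupling is the weighted circular mean vector of
that distribution,

    R e^{iθ} = Σ_k r(φ_k) e^{iφ_k} / Σ_k r(φ_k),

with R ∈ [0, 1] the phase-locking strength and θ the preferred phase.
For a rate r(φ) ∝ 1 + m·cos(φ − φ₀), the asymptotic R is m/2.
Significance uses a spike-time jitter null: every spike shifted by
uniform(−0.5, +0.5) s, R recomputed, 100 iterations; a unit is
phase-locked to a limb when its real R exceeds more than 95% of the
jittered ones. Vector lengths above 0.9 are treated as outliers and the
unit is excluded from all coding analyses.

**Start/stop and speed coding.** Per movement event, the mean rate in a
−5..−1 s baseline window is compared with the rate within ±0.5 s of the
event (paired t-test); the modulation index is
|FR_event − FR_baseline| / FR_baseline on the baseline-normalized mean
PSTH (20 ms bins). Speed tuning bins body speed in 10 mm/s steps; the
speed score is |Pearson r| of rate versus bin speed against a
bin-shuffle null.

**Optogenetic tagging.** After removing sub-millisecond laser
artifacts, a unit is tagged when it shows (1) a significant excitatory
response within 6 ms of laser onset, (2) Pearson r > 0.95 between
evoked and baseline mean waveforms, and (3) an evoked/baseline
trough-amplitude ratio < 2.

**Synthetic sessions.** `gaitphase.synth` generates pose tracks with a
lateral-sequence gait (footfall order LR→LF→RR→RF, diagonal limbs in
phase), bout-structured locomotion, healthy and dopamine-lesion
kinematic regimes, and inhomogeneous-Poisson spike trains with known
phase/speed/start modulation and laser-evoked responses — so every
stage of the pipeline is testable against ground truth without any
recorded data.

## Worked example

```python
from gaitphase import SessionConfig, analyze_session
from gaitphase.synth import generate_cohort

cfg = SessionConfig(rng_seed=7)
session = generate_cohort("healthy", n_mice=1, n_units=6, seed=7, duration_s=300.0)[0]
result = analyze_session(session.pose, session.spikes, cfg, laser=session.laser)
for key, value in sorted(result.summary().items()):
    print(f"{key}: {value:.3f}" if isinstance(value, float) else f"{key}: {value}")
```

prints (abridged):

```
frac_phase_locked: 1.000
frac_speed: 0.333
frac_start_stop: 1.000
initiation_rate_per_min: 3.600
lr_n_strides: 410
mean_speed_mm_s: 80.728
n_tagged: 4
n_units: 6
n_walking_bouts: 18.000
```

The 300 s session contains 18 walking bouts and ~400 strides per limb.
All six simulated units carry cosine phase modulation, and all are
flagged phase-locked by the jitter test; four of the six are
ground-truth opsin-expressing units and exactly those four pass the
three tagging criteria. Per-unit detail lives in
`result.cell_metrics` (one row per unit: per-limb vector length/angle
and jitter p, start/stop p and modulation indices, speed score,
tagging outcome):

```
unit_id  max_vector_length preferred_limb  phase_locked_any  tagged
   u000              0.182             lf              True    True
   u001              0.162             lr              True    True
   u002              0.172             lf              True   False
   ...
```

The same pipeline is scriptable from the shell:

```sh
gaitphase --seed 7 --out-dir session simulate --regime healthy --duration 300 --n-units 6
gaitphase --seed 7 --out-dir out all --pose session/pose.csv --spikes session/spikes.csv \
          --laser session/laser.csv --waveforms session/waveforms.csv
```

which writes `cell_metrics.csv`, `strides.csv`, `bouts.csv` and a
`run.yaml` sidecar recording the full configuration and seed.

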