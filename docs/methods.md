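# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. All constants live in
`gaitphase.config.SessionConfig`; a run is fully described by one
(config, seed) pair, and outputs carry a YAML sidecar recording both.

## Kinematic analysis

**Units and time.** Pose coordinates are converted from pixels to mm at
load (0.3 mm/pixel default) and never handled in pixels downstream.
Frame time is derived from the frame index at a fixed 80 Hz camera
clock; no per-row timestamps are stored. Frames with any missing body
part are flagged invalid and excluded from bouts and strides; the
dropout fraction is logged.

**Body speed and heading.** Speed is the norm of the frame-to-frame
derivative of the six-part average position, smoothed with a 0.25 s
moving average before thresholding — the raw 80 Hz derivative chatters
across the bout thresholds. Heading is taken from the *smoothed
velocity vector*, not the raw one: during walking the instantaneous
centroid velocity direction is dominated by residual limb-oscillation
components and is meaningless frame to frame. Positive heading change
is counterclockwise in the image plane and labeled contraversive (for a
right-hemisphere implant viewed bottom-up); a config flag
(`contraversive_ccw`) flips the convention, since camera mirroring
cannot be inferred from data.

**Motion and walking bouts.** Runs with speed > 50 mm/s lasting
≥ 0.3 s (the minimum applies to this suprathreshold core, before any
extension) are extended backward/forward through all samples
≥ 20 mm/s; touching or overlapping extended bouts are merged. Manual
acceptance of "real" walking is replaced by an automated surrogate: a
bout is *walking* when at least 3 of 4 limbs have a rhythmicity index
(spectral power of the raw projection in 1–8 Hz over total power up to
20 Hz) ≥ 0.5. Bouts shorter than 2 s stay "motion" — fewer than two
cycles at the 1 Hz band floor cannot support a rhythmicity judgment.

**Limb projection.** Each limb is projected onto the nose→tail unit
vector, relative to the *nose–tail midpoint*. The body reference
deliberately excludes the limbs: a six-part centroid feeds every limb's
oscillation back into every projection, and because diagonal limbs
cycle ~10° apart, the neighbor's stance corner lands just before a
limb's own corner and biases its detected onset by about half a frame.
The projection grows toward the tail, so the minimum is the limb's
anterior extreme — the stance onset — and the maximum is the swing
onset.

**Stride segmentation.** Coordinates are smoothed with a 3rd-order,
7-frame (87.5 ms) Savitzky–Golay filter — the window preserves content
up to the 8 Hz top of the gait band. The projection is band-passed
0.5–8 Hz with a 3rd-order Butterworth applied forward–backward
(zero-phase; onsets are timing-critical). Local extrema need ≥ 62.5 ms
separation (half-period at 8 Hz) and ≥ 0.5 mm prominence; on a
same-kind adjacency the lower-prominence extremum is dropped, so kept
extrema strictly alternate. A min→max→min triple within one walking
bout whose duration lies in [0.125, 2] s (the band's period range) is a
stride.

**Sub-frame onset refinement.** Band-limiting a ~3 Hz
asymmetric-duration cycle to 8 Hz keeps only two harmonics and
symmetrizes the waveform, shifting detected maxima about one frame
toward mid-cycle; a discrete argmin under tracking noise is further
biased toward the shallow side of each corner. Both biases corrupt the
swing:stance ratio (recovered as ~0.95 instead of a true 0.818) while
leaving stance-onset *matching* acceptable. The projection around an
onset is a corner — two near-linear segments of different slope — so
each band-passed extremum is refined by a broken-stick least-squares
fit (basis {1, min(x−b,0), max(x−b,0)}) to the *raw* projection in a
±4-frame window, with the breakpoint b searched on a 0.25-frame grid
over ±2 frames. The breakpoint is a consistent estimator of a noisy
corner; with it the ratio recovers to 0.82–0.83. Refinements that would
reorder the extremum sequence fall back to the band-passed location.
Stride length is the Euclidean displacement of the limb between the two
stance onsets measured on the smoothed (not band-passed) track — the
band-pass removes the translation that stride length must include.

**Limb phase.** Within a stride, phase rises linearly from 0° at
stance onset to 360° at the next stance onset; a frame lying exactly on
an onset gets phase 0. Frames outside accepted strides are invalid and
never contribute to phase coding.

## Neural analyses

**Phase histogram and vector.** Spikes are assigned to frames by
flooring the spike time and counted only when that frame has valid
phase. Rate per 15° bin = spikes/frames × frame rate; this occupancy
correction is why the mean vector is computed from the binned *rate*
distribution rather than raw spike phases — raw phases would inherit
any non-uniform phase coverage. For a cosine rate profile evaluated at
the 24 equally spaced bin centers, discrete orthogonality makes the
estimator exact: R = m/2, θ = φ₀ (to 1e-12; the only residual bias is
the within-bin cosine average, a factor sinc(π/24) ≈ 0.9971).

**Jitter significance.** Each of 100 iterations adds i.i.d.
uniform(±0.5 s) offsets to every spike *in time*, so jittered spikes
re-enter the full frame/phase assignment (some leave the stride mask
and drop out; slow rate structure survives into the null). Frame counts
are unchanged by spike jitter. Significance is the 95% exceedance rule;
the reported p uses the add-one convention p = (1+#{R_jit ≥ R})/(1+n)
with ties counted toward the null. Units with fewer than 50 valid-phase
spikes, or limbs with fewer than 30 strides, are untestable — these
eligibility floors are package additions. Per-(unit, limb) RNG
substreams are derived from the session seed, so results are
independent of unit ordering.

**Outliers and classification.** A unit whose maximum per-limb R
exceeds 0.9 is an outlier and excluded from all coding analyses. A unit
is phase-locked if any limb's jitter test is significant; the preferred
limb is the one with maximal R; when exactly two limbs are locked, the
diagonal-pair flag records whether they form LF+RR or RF+LR.

**Start/stop coding.** Events need their whole −5..+2 s peri-event span
in-session; at least 5 eligible events are required (package addition).
The paired t-test compares per-event baseline (−5..−1 s) and event
(±0.5 s) mean rates, two-sided; identical paired values are untestable
rather than p = 1. The modulation index normalizes the cross-event mean
PSTH by its baseline mean and takes the *maximum of the mean PSTH* in
20 ms bins within ±0.5 s — per-event maxima would inflate the index.
The index carries a positive max-of-noise bias on flat PSTHs, visible
in the calibration tests; it is exact (1.0) on noiseless rate doublings
and invariant to uniform rate rescaling.

**Speed coding.** The same smoothed full-session speed series used for
bout detection is binned in 10 mm/s steps; bins occupied under 1 s are
dropped (package addition) and at least 3 usable bins are required. The
score is |Pearson r| of bin rate versus bin center; significance by
default uses the 100-fold bin-shuffle null (the parametric Pearson p is
also computed and can be selected via `speed_significance="pearson"`).
The score is linear by construction: U-shaped tuning scores low.

**Angular permutation test.** The statistic is the Euclidean distance
between the two groups' mean resultant vectors (unit weight per
sample); labels are shuffled 1000 times; add-one p, ties toward the
null. Bonferroni correction is a separate helper. The add-one and tie
conventions are conservative choices, not inferred from any source.

**Optogenetic tagging.** Spikes within 0.6 ms of a pulse onset are
removed first (photoelectric artifacts). The response window is
(0.6 ms, 6 ms] after onset versus a matched-duration window immediately
before the pulse; the test is a one-sided paired t-test requiring
excess spiking (a per-pulse exact sign test is available via
`tag_test="binomial"` for very low rates). Latency is the median over
responsive pulses of the first spike in the response window. Tagging
requires all three criteria (response p < 0.05 with latency ≤ 6 ms,
waveform r > 0.95, trough-amplitude ratio < 2); the D1/D2 label itself
comes from session metadata (which Cre line was recorded), never from
the data.

## Synthetic data generator

The generator reproduces the *statistical structure* the analysis
consumes, not biomechanics.

**Gait.** A master oscillator advances at a per-stride frequency drawn
from N(3, 0.3²) Hz (healthy) and each limb's stance onsets are the
oscillator's offset crossings (LR 0°, LF 170°, RR 190°, RF 350° —
lateral-sequence order, diagonal pairs near in-phase, ipsilateral
front/rear near anti-phase). Optional per-stride timing jitter
(`offset_jitter_deg`, SD in cycle degrees) models stride-to-stride
inter-limb variability; it is 0 by default so that kinematic validation
sees a strictly ordered footfall sequence, and 20° in the cohort
presets so that limb phases decorrelate enough for single-limb
preference to be meaningful. Within a cycle the limb's body-frame
position is a piecewise-linear sawtooth — posterior drift at body speed
during stance (1 − swing_fraction = 0.55 of the cycle), anterior return
during swing — making the swing:stance ratio an explicit parameter;
peak-to-peak amplitude is stride length × stance fraction. The waveform
is smoothed with a 3-frame moving average: enough to round the corners
that extrema detection faces, chosen deliberately narrow because wider
symmetric kernels measurably displace the extrema of an
asymmetric-duration cycle and would make the emitted waveform
contradict the generator's own stride truth. Stride length follows
speed as L = L₀/(1 − c·f) (L₀ = 45 mm, c = 0.05 s healthy), body speed
= f·L ≈ 160 mm/s. Walking epochs have trapezoidal speed envelopes
(0.25 s ramps); ground-truth bout boundaries are the programmed 20 mm/s
crossings; ground-truth strides are crossings whose full cycle lies in
the constant-speed plateau. Quiescent epochs jitter the centroid at
3 mm/s SD, well under the 20 mm/s hysteresis floor. Heading integrates
a turning bias plus noise (8°/√s); near walls the animal steers toward
the center — in its bias direction when one exists, since a lesioned
animal circles along the wall ipsiversively. Tracking noise is 0.3 mm
(≈1 pixel) per part per frame.

**Regimes.** Healthy and sham share one preset. The 6OHDA preset:
stride frequency 2 ± 0.35 Hz, L₀ = 30 mm, swing fraction 0.35 (limbs
longer on the ground), bout rate 1.5/min, turning bias −15°/s
(ipsiversive). Neuron populations: modulation depth m ~ N(0.35, 0.05²)
for all cell types in healthy/sham; the 6OHDA preset raises the D2 mean
to 0.50 and lowers the D1 start gain from 1.5 to 0.8 (D2 start gain
0.8 throughout). Bout-duration distributions (N(8, 3²) s healthy,
N(6, 2.5²) s lesion, clipped at 2.5 s) are plausible stand-ins — no
quantitative source exists — and are flagged as such in `truth.json`.

**Spikes.** Inhomogeneous Poisson by thinning against the rate maximum,
with rate

    r(t) = r0 · Π_limb (1 + m cos(φ_limb(t) − φ0))
              · max(0.1, 1 + β (v − v̄)/v̄)
              · (1 + γ exp(−(t − t_start)²/2σ²)) · (stop term alike)

floored at 0.1·r0; phase factors are 1 outside walking. The rate is
piecewise-constant on the frame grid so the analyzer's floor-to-frame
spike assignment sees exactly the programmed phase. The multiplicative
form and the clipping are a test-harness design, not a claim about MSN
encoding. For a single modulated limb, spike density ∝ 1 + m·cos(φ−φ₀)
under uniform phase occupancy, giving asymptotic R = m/2 — the
analytic target the estimator tests recover.

**Laser.** Tagged units gain ≤ 1 extra spike per pulse with probability
`evoke_prob` (0.8) at a latency from N(3.5, 1²) ms truncated to
[2, 6] ms — evoked responses never precede 2 ms, so the 0.6 ms
artifact exclusion cannot bite. Mean waveforms are a per-unit biphasic
template; the evoked mean is the template × `evoked_amp_factor` plus
noise whose SD scales as (40 µV)/√n with the number n of laser-window
spikes. This matters for specificity: an untagged unit's "evoked mean
waveform" is estimated from a handful of chance spikes and is therefore
noisy, which is exactly what degrades its waveform correlation in
practice.

## What passing tests do and do not show

The generator's limbs are rigid oscillators with piecewise-linear
kinematics, Gaussian tracking noise, and no grooming, rearing, missing
frames beyond random dropouts, posture changes, or electrode drift.
Passing recovery tests therefore demonstrates the *correctness of the
algorithms against their own definitions* (segmentation finds the
events the waveform encodes; the estimator converges to m/2; the nulls
are calibrated), not performance on real video or real spike sorting.
In particular, the rhythmicity surrogate for walking acceptance is
validated only against simulated grooming (high-frequency jitter), and
the tagging specificity result depends on the generator's waveform
noise model.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sessions chosen by the package:
120 s kinematic-validation sessions (~450 strides/limb), ~320 s
near-continuous walking sessions for spike-estimator tests (≥ 20 000
valid-phase spikes at 70 Hz), 200 null units for jitter calibration,
500 replicates for permutation calibration, a 40-unit tagging cohort,
and 3–4 mice × 12 units × 360 s per regime for the cohort contrasts.
The acceptance script uses slightly smaller Monte-Carlo sizes (its
`n` fields record them) and finishes in well under a minute.

Degenerate inputs are flagged, not guessed at: zero-length nose–tail
axes give NaN projections; sessions without walking produce untestable
phase results while event and speed analyses still run; empty bout
lists give zero initiation rates; zero-variance paired differences and
zero baselines are untestable rather than p = 1 or division errors.
Permutation/shuffle p-values use the add-one convention throughout, so
p = 0 never occurs.

## Known limitations

- Phase is assigned frame-wise (floor), not interpolated to spike time;
  at 80 fps a frame spans ~13° of a 3 Hz cycle, below the 15° bin width.
- The modulation index inherits a positive max-of-noise bias that grows
  as event counts shrink; indices from few events should be compared
  only between equally-sized event sets.
- The speed score is linear; non-monotonic tuning is under-reported.
- The walking classifier is a spectral surrogate for manual curation
  and has only been validated on synthetic non-gait controls.
- Heading-change statistics are noisy at the session level when bouts
  repeatedly engage the arena walls; regime-level contrasts average
  over sessions.
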