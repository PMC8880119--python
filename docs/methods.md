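# Methods

This note documents the models, numerical choices and limitations behind
`tensiowork`, stage by stage.

## Tensiometry signal chain

Raw input is a two-channel accelerometer stream (default 50 660 Hz per
channel) carrying one shear-wave burst per tendon tap (2 ms burst, 10 ms
repetition). Processing:

1. **Band-pass** 150–1500 Hz, 4th-order Butterworth, applied zero-phase
   (forward–backward). Zero-phase filtering is chosen because analysis is
   offline and tap timing anchors every later delay estimate; a causal
   filter would shift all taps by its group delay.
2. **Tap detection** by matched filtering: a representative tap template
   (by default the highest-energy 2 ms segment of channel 1) is
   cross-correlated with channel 1; peaks above an adaptive threshold
   (10 × the MAD of the correlation stream) separated by ≥ 5 ms are tap
   events. An auto-extracted template always matches its own source
   segment perfectly — even in tap-free noise — so a trial counts as
   tap-bearing only if the template also matches elsewhere; otherwise the
   result is empty (with a warning, not an exception).
3. **Travel time per tap**: normalized cross-correlation of the two 4 ms
   post-tap windows (both anchored at the channel-1 tap time). The
   integer-lag argmax is refined by fitting a cosine through the peak and
   its two neighbours; for the correlation of narrowband bursts this is
   the natural peak model and resolves delays well below the sample
   period (measured maximum error ≈ 0.4% of the sample period on
   noiseless band-limited fractional shifts, against the ≤ 1% theoretical
   claim for this estimator class).
4. **Wave speed** = 8 mm spacing / travel time. Taps with non-positive
   delay, peak correlation below 0.5, or speed outside [2, 150] m/s are
   flagged invalid and linearly interpolated (flag retained). The quality
   floor and speed bounds are plausibility guards, config-exposed; a
   trial in which *every* tap fails raises an error naming the trial,
   mirroring a sensor-contact failure. If both sides were instrumented,
   the series with the higher mean peak correlation would be preferred.

## Calibration

Net ankle moment during standing sway is M(t) = F_z(t) · (COP_ap(t) −
ankle axis). Only the vertical force enters the lever product (shear
force is not available from the plate channels used). The wave-speed
stream is aligned to the plate clock via the manual-strike spike
(cross-correlation of the spike-bearing streams; a spike must exceed 5 ×
the stream MAD) and resampled to 1000 Hz by linear interpolation. The
calibration is an ordinary least-squares fit of M on S² over raw paired
samples (≥ 100 required), not cycle averages. Samples within 0.1 s of the
strike are dropped from the fit. Session-start and session-end fits are
compared; relative changes in either coefficient beyond 15%
(config-exposed; the choice of threshold is ours) set a drift flag.

## Sync alignment

The IMU and tensiometry recorders are started by a wireless trigger with
non-deterministic latency; the tensiometry clock starts up to ~100 ms
late. During early stance both the ankle angle and the tendon load rise
from heel strike, so the offset is estimated per level stride
(|slope| < 1°, the 0° bin) as the lag, searched over ±150 ms on a 1 ms
grid, maximizing the per-lag-normalized correlation between the z-scored
ankle-angle window (first 10% of the gait cycle) and the wave-speed
stream. The trial offset is the mean over ≥ 5 level strides; it is then
subtracted from the wave-speed clock. z-scoring per window makes the
match scale- and offset-free; the ±150 ms bound adds margin over the
largest physical latency. Angle (not its derivative) is correlated.

Measured performance on synthetic trials with injected delays uniform in
10–100 ms: mean absolute residual ≈ 0.1% of the gait cycle (tolerance
1%).

## Gait events and slope context

* **Heel strikes**: 10–50 Hz band-pass, Hilbert amplitude envelope
  smoothed over 50 ms, peak picking with three guards: prominence ≥ 2 ×
  envelope MAD, prominence ≥ 25% of the envelope excursion (a sparse
  impact train has near-zero MAD, which would otherwise admit
  filter-ripple peaks), and height ≥ 4 × the median envelope (impacts
  must dwarf the typical level, which rejects stationary noise). Each
  peak is then back-tracked to its half-height onset, since the envelope
  maximum trails the impact by the burst rise time plus half the
  smoothing window. Detected events land within ~20 ms of true impact
  onset on synthetic data (tolerance ±30 ms). The minimum stride time
  (0.4 s) and all thresholds are config-exposed.
* **Stride metrics**: stride time between successive heel strikes, length
  = horizontal pelvis displacement over the stride, speed = quotient.
  Strides longer than 3 m are excluded (`stride_length_gt_3m`) as IMU
  reconstruction errors.
* **Course map**: the outward and return mapping passes are each rescaled
  to the surveyed course length; the return pass is mirrored onto outward
  coordinates with its incline sign flipped; the two are averaged on a
  0.5 m grid and a 2 m moving median removes single-point glitches.
* **Slope assignment**: course incline interpolated at the stride's
  midpoint displacement (the sampling point within the stride is our
  choice). Bins are the nearest even degree, ties resolved toward zero so
  extreme bins are not inflated; binning is odd-symmetric by
  construction. Strides whose midpoint falls off the mapped course are
  excluded (`off_course`). Masked course intervals (e.g. a crosswalk)
  are supported by simply excluding off-map strides.

In the pipeline, stride segmentation and slope assignment run *before*
sync correction, because the sync stage needs to know which strides are
level; the wave-speed clock correction does not affect the
kinematics-side stride boundaries.

## Muscle–tendon mechanics

Moment arms (m) from joint angles (degrees):

    R_ankle(θ) = 1.4e-6·θ² − 1.7e-4·θ + 4.4e-2
    R_knee(Φ)  = −2.0e-6·Φ² + 3.8e-4·Φ + 1.8e-2

**Units.** The polynomials take degrees, but a moment arm times an
angular rate is a linear velocity only if the rate is in rad/s. The API
therefore takes angular velocities in rad/s, and the excursion integrals
(closed-form integrals of the polynomials over angle) carry a π/180
factor. This is the only dimensionally consistent reading and is asserted
by the property test that the excursion derivative with respect to the
angle *in radians* reproduces the moment arm.

Angular velocities are obtained by central differencing after a 6 Hz
zero-phase low-pass (gait kinematics carry little power above ~6 Hz; the
differentiation scheme is our choice). Negative moments are clipped to
zero force — a tendon transmits tension only — with a clip counter
logged. Work is integrated trapezoidally over the full stride (stance +
swing); positive and negative work integrate the positive and negative
parts of power, so net = pos + neg holds to machine precision. Work
against gravity per step is 0.5·g·L·tan(slope) per kg (half the
elevation gain per stride). Work loops are force–excursion paths ordered
from heel strike and closed; the shoelace signed area (counter-clockwise
positive) equals −∮F dL, which is the net work; agreement with the
time-domain integral is held to 1e-3 J/kg on synthetic strides.

## Slope statistics

Wave-speed curves are resampled to a 101-point 0–100% gait-cycle grid
(standard convention), normalized to the participant's mean per-stride
peak over level strides, and averaged across participants per 2° bin.
Per-stride net work is zero-referenced by subtracting the participant's
level-condition mean, then pooled across participants and regressed on
slope by OLS, separately for declines (slope ≤ 0) and inclines
(slope ≥ 0). Level strides enter both segments — the boundary assignment
is ambiguous in principle, and symmetric inclusion keeps the two fits
balanced (config-exposed). No mixed-effects structure and no
multiple-comparison correction are applied; zero-referencing is the
stated device for removing participant-level offsets.

## Synthetic data generator

The generator emulates the study conditions so that each stage's output
can be checked against retained truth:

* **Gait templates** are phenomenological periodic splines (ankle dip →
  dorsiflexion rise → push-off plantarflexion; stance and swing knee
  flexion waves; single-peaked tendon load with a late-swing passive
  rise). They are not forward-simulated dynamics. Over the first 12% of
  the gait cycle the wave-speed template is an exact affine function of
  the ankle-angle template; this encodes the empirical early-stance
  alignment of the two signals that the sync stage exploits. Without it,
  cross-correlating two unrelated shapes would have an irreducible bias
  that real data evidently did not have. Slope modulators scale ankle
  amplitude and load with slope (+1%/°), knee flexion with |slope|
  (+0.8%/°), and stride length/time with slope (+1%/°, leaving speed
  roughly constant) — directions follow the observed trends, magnitudes
  are our choice.
* **Defaults** mirror the cohort means: level speed 1.31 m/s, stride
  length 1.60 m, body mass 76.5 kg, calibration (0.05, −17.0). Kinematic
  noise defaults to 1% of signal amplitude (≈ 0.25° on the ankle trace,
  inside the 0.75° pitch accuracy of commercial IMUs). The synthetic IMU
  rate is 120 Hz so the 10–50 Hz heel-strike band sits strictly below
  Nyquist.
* **Tap rendering** evaluates an analytic raised-cosine-windowed 800 Hz
  burst (2 ms, inside the 150–1500 Hz analysis band) at the exact delayed
  sample times, so subsample delays are realized without rounding and
  genuinely exercise the cosine-fit estimator. The burst's spectral shape
  is an assumption — only its timing is documented for the real device.
  Channel 2 is attenuated 0.5× with twice the additive noise (the wave
  decays as it propagates); the noise scale is a fraction of the
  channel-1 peak (device noise floors span ~1e-6 to 3.2e-5). A half
  tap-interval pre-roll keeps the first burst off the array edge.
* **Start delay**: the tensiometry clock starts `sync_delay` late, so a
  physical event at kinematic time t appears at tensiometry time
  t − sync_delay; the sync stage should estimate −sync_delay, and the
  truth dict carries that expectation explicitly.
* **Courses** are piecewise-constant section inclines with 5 m smoothstep
  blends, mirrored with sign flip onto the return half. Section inclines
  are chosen to cover every 2° bin magnitude up to the cap before random
  fill, so binned analyses are exercised across the full range. At the
  turnaround point the incline flips discontinuously, as it does when a
  walker turns around.
* **Cohort work sets** emit, per stride, strictly positive force streams
  and velocity streams whose product integrates exactly (trapezoid-exact)
  to W_level + sens·slope + N(0, σ_w), with the sensitivity switching at
  0° (knot matching the separate incline/decline fits). Velocities are
  made cyclic (zero net excursion) by adding a force-orthogonal
  correction, so work loops close as they do in steady gait, without
  changing the stride work. Per-participant level-work offsets
  (SD 0.05/0.03 J/kg for soleus/gastrocnemius, settable to zero) exercise
  the zero-referencing stage end to end. Default sensitivities are
  soleus +0.02 (decline) / +0.01 (incline) and gastrocnemius +0.008 /
  −0.008 J/kg per degree with 0.05 J/kg work noise.
* **Sway trials**: anterior–posterior COP oscillation ahead of the ankle
  axis, Fz ≈ body weight with a slow ripple, a decaying manual-strike
  spike whose onset marks the impact sample, and wave-speed truth from
  the participant's inverse calibration.

All generator randomness flows from explicit seeds; identical seeds give
byte-identical outputs (asserted). In the pipeline, one root seed feeds
named substreams per module.

### What passing synthetic tests does not show

The generator reproduces the sensors' sampling structure, noise scales
and timing pathologies, but not: soft-tissue artifact, tendon-contact
dropouts, IMU drift and reconstruction failures, inter-stride
variability beyond the configured noise, non-affine early-stance
load–angle relationships, or muscle-vs-tendon length partitioning.
Passing tests therefore validate the *processing chain* (signal →
calibration → sync → segmentation → mechanics → statistics), not the
physiological accuracy of the templates.

## Problem sizes

Default test and demo sizes are chosen for desk-scale runs: 2
participants × 40 strides in the demo pipeline (fast mode synthesizes the
wave-speed series directly; the 50.66 kHz tap-rendering path is exercised
on short trials), 20 × 10-stride trials for the sync sweep, and 11 × 200
strides for the cohort regression — the last matching the cohort
dimensions the statistics are specified for.

## Known limitations

* The 65/35 PCSA force split is constant across time, posture and
  participants; no EMG, force–length or force–velocity modeling.
* Muscle and tendon length changes are not separated (MTU level only).
* No device drivers or live streaming; the pipeline is offline.
* The course map assumes laps of a single mapped course; GPS-free
  positioning relies on cumulative pelvis displacement.
* Regressions pool strides across participants (no mixed effects).
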