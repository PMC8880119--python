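"""Synthetic gait-and-sensor generator.

Generates every input the pipeline consumes — tendon-tap accelerometer
recordings, joint-kinematics streams, balance-plate sway trials, a sloped
out-and-back course, and a cohort work set — with the ground truth
retained, so every processing stage can be verified end to end without
any recorded data.

What is emulated
----------------
* Two-channel tap recordings at ~50.66 kHz/channel: a 2 ms raised-cosine
  windowed burst every 10 ms on channel 1, repeated on channel 2 after the
  shear-wave travel delay (8 mm spacing divided by the instantaneous wave
  speed), attenuated and with more additive noise (the shear wave decays
  as it propagates).  Subsample delays are realized exactly by evaluating
  the analytic burst waveform at the delayed times.
* Joint kinematics (ankle dorsiflexion, knee flexion, pelvis displacement)
  at IMU rate with slope-dependent gait-pattern modulation and additive
  angle noise at the pitch-accuracy level of commercial IMUs.
* A non-deterministic inter-system start delay: the tensiometry clock
  starts ``sync_delay`` seconds after the kinematic clock.
* Balance-plate sway trials (vertical force + center of pressure at
  1000 Hz) with a manual impact spike for clock alignment.
* An out-and-back course whose outward incline profile mirrors (with sign
  flip) onto the return pass.

The default gait templates are phenomenological: smooth periodic curves
with the qualitative features of walking (early-stance dorsiflexion rise,
push-off plantarflexion, swing-phase knee flexion, a single-peaked tendon
load).  Over the first ~12% of the gait cycle the wave-speed template is
an exact affine function of the ankle-angle template, reflecting the
empirical early-stance alignment of the two signals that the
cross-correlation sync stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .calibration import MEAN_C0, MEAN_C1
from .gait import CourseMap, bin_slope
from .tensiometry import (AccelRecording, DEFAULT_FS, DEFAULT_SPACING,
                          DEFAULT_TAP_INTERVAL, WaveSpeedSeries)

#: synthetic IMU/kinematics sample rate, Hz (keeps the 10-50 Hz heel-strike
#: band strictly below Nyquist)
IMU_FS = 120.0
#: cohort-mean level-walking gait parameters
LEVEL_SPEED = 1.31          # m/s
LEVEL_STRIDE_LENGTH = 1.60  # m


# ---------------------------------------------------------------------------
# profiles, patterns, trial specs

@dataclass
class ParticipantProfile:
    """Per-participant anthropometrics and calibration ground truth."""

    id: str = "P00"
    mass: float = 76.5                      # kg
    calib_slope: float = MEAN_C1            # N*m per (m/s)^2
    calib_intercept: float = MEAN_C0        # N*m
    level_stride_length: float = LEVEL_STRIDE_LENGTH  # m
    level_speed: float = LEVEL_SPEED        # m/s

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.calib_slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not (0 < self.level_stride_length <= 3.0):
            raise ValueError("stride length must lie in (0, 3] m")

    @property
    def level_stride_time(self) -> float:
        return self.level_stride_length / self.level_speed


@dataclass
class GaitPattern:
    """Periodic per-gait-cycle templates plus slope modulators.

    Templates are sampled on ``pct`` (0..100 % gait cycle, first == last
    sample).  ``slope_modulators`` holds fractional per-degree scaling
    coefficients applied per stride:

    * ``ankle_scale``  — ankle amplitude grows with slope,
    * ``knee_scale``   — knee flexion grows with |slope|,
    * ``speed_scale``  — wave speed (hence load) grows with slope,
    * ``length_scale`` / ``time_scale`` — stride length and time grow with
      slope so walking speed stays roughly constant.
    """

    pct: np.ndarray
    ankle_template: np.ndarray    # degrees
    knee_template: np.ndarray     # degrees
    speed_template: np.ndarray    # m/s (tendon shear-wave speed)
    moment_template: np.ndarray   # N*m (reference calibration applied)
    slope_modulators: dict = field(default_factory=lambda: {
        "ankle_scale": 0.012, "knee_scale": 0.008,
        "speed_scale": 0.010, "length_scale": 0.010, "time_scale": 0.010,
    })

    def __post_init__(self) -> None:
        for name in ("ankle_template", "knee_template",
                     "speed_template", "moment_template"):
            tpl = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, tpl)
            if tpl.shape != self.pct.shape:
                raise ValueError(f"{name} must match the pct grid")
            if abs(tpl[0] - tpl[-1]) > 1e-6 * max(1.0, np.abs(tpl).max()):
                raise ValueError(f"{name} must be periodic (first == last sample)")

    def curves_at(self, slope_deg: float):
        """Slope-modulated (ankle_deg, knee_deg, speed_mps) templates."""
        m = self.slope_modulators
        ankle = self.ankle_template * (1.0 + m["ankle_scale"] * slope_deg)
        knee = self.knee_template * (1.0 + m["knee_scale"] * abs(slope_deg))
        speed = self.speed_template * (1.0 + m["speed_scale"] * slope_deg)
        return ankle, knee, speed

    def stride_geometry(self, slope_deg: float, profile: ParticipantProfile):
        """(stride_length_m, stride_time_s) at the given slope."""
        m = self.slope_modulators
        length = profile.level_stride_length * (1.0 + m["length_scale"] * slope_deg)
        time = profile.level_stride_time * (1.0 + m["time_scale"] * slope_deg)
        return length, time


def _periodic_spline(knots_pct, knots_val, pct):
    k = np.asarray(knots_pct, dtype=float)
    v = np.asarray(knots_val, dtype=float)
    cs = CubicSpline(k, v, bc_type="periodic")
    return cs(pct)


#: gait-cycle fraction over which wave speed tracks ankle angle affinely
EARLY_STANCE_PCT = 12.0
_S_BASE = 22.0      # m/s, wave speed at heel strike
_S_PER_DEG = 1.5    # m/s per degree of dorsiflexion, early stance


def default_gait_pattern(n_points: int = 201) -> GaitPattern:
    """Level-walking templates on a dense % gait-cycle grid.

    Ankle: small plantarflexion dip after heel strike, dorsiflexion rise
    through midstance, push-off plantarflexion, swing return.  Knee: stance
    flexion wave and a large swing flexion peak.  Wave speed: affine in the
    ankle angle over the first 12% of the cycle, then a single stance peak
    and a modest late-swing rise (passive stretch), back to baseline.
    """
    pct = np.linspace(0.0, 100.0, n_points)
    ankle = _periodic_spline(
        [0, 4, 12, 30, 45, 55, 62, 75, 88, 100],
        [0, -2.5, 6, 8.5, 10, -2, -15, -6, 1.5, 0], pct)
    knee = _periodic_spline(
        [0, 8, 15, 30, 45, 60, 70, 80, 92, 100],
        [5, 16, 14, 8, 6, 35, 60, 32, 7, 5], pct)
    # wave speed: exact affine tracking of the ankle template in early
    # stance, plus a smooth bump (zero and flat below EARLY_STANCE_PCT)
    # carrying the stance load peak and the late-swing passive stretch
    bump = np.zeros_like(pct)
    late = pct >= EARLY_STANCE_PCT
    bump[late] = _periodic_spline(
        [EARLY_STANCE_PCT, 25, 45, 62, 75, 90, 100],
        [0, 4, 8, 20.5, 16, -1, 0], pct[late])
    speed = _S_BASE + _S_PER_DEG * ankle + bump
    moment = MEAN_C1 * speed**2 + MEAN_C0
    return GaitPattern(pct=pct, ankle_template=ankle, knee_template=knee,
                       speed_template=speed, moment_template=moment)


@dataclass
class TrialSpec:
    """Conditions of one synthetic walking trial."""

    n_strides: int
    slope_sequence: np.ndarray      # degrees, one per stride
    sync_delay: float = 0.0         # s, tensiometry clock starts this late
    noise_scale: float = 0.01       # fraction of signal amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        self.slope_sequence = np.atleast_1d(
            np.asarray(self.slope_sequence, dtype=float))
        if self.slope_sequence.size == 1 and self.n_strides > 1:
            self.slope_sequence = np.full(self.n_strides,
                                          self.slope_sequence[0])
        if self.slope_sequence.size != self.n_strides:
            raise ValueError("slope_sequence must have one entry per stride")
        if np.any(np.abs(self.slope_sequence) > 10.0):
            raise ValueError("slopes must lie within [-10, +10] degrees")
        if not (0.0 <= self.sync_delay <= 0.1):
            raise ValueError("sync delay must lie within [0, 0.1] s")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be non-negative")


@dataclass
class JointKinematicsSeries:
    """Sampled joint-kinematics streams on the kinematic clock."""

    times: np.ndarray        # s
    ankle_deg: np.ndarray
    knee_deg: np.ndarray
    pelvis_x: np.ndarray     # m, cumulative horizontal displacement
    fs: float = IMU_FS
    foot_accel: np.ndarray | None = None  # impact-bearing channel for heel strikes


@dataclass
class SyntheticTrial:
    """One generated walking trial with full ground truth."""

    kinematics: JointKinematicsSeries
    wave_speed_stream: WaveSpeedSeries   # on the (late) tensiometry clock
    truth: dict


def _phase_arrays(spec: TrialSpec, profile: ParticipantProfile,
                  pattern: GaitPattern):
    """Per-stride (start_time, stride_time, stride_length, slope)."""
    lengths, times = [], []
    for s in spec.slope_sequence:
        length, time = pattern.stride_geometry(s, profile)
        lengths.append(length)
        times.append(time)
    starts = np.concatenate([[0.0], np.cumsum(times)[:-1]])
    return starts, np.asarray(times), np.asarray(lengths)


def _eval_gait(t, starts, stride_times, slopes, pattern: GaitPattern,
               what: str):
    """Evaluate a slope-modulated template stream at arbitrary times."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t)
    edges = np.concatenate([starts, [starts[-1] + stride_times[-1]]])
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                  len(starts) - 1)
    for i in np.unique(idx):
        m = idx == i
        phase = (t[m] - starts[i]) / stride_times[i] * 100.0
        phase = np.clip(phase, 0.0, 100.0)
        ankle, knee, speed = pattern.curves_at(slopes[i])
        src = {"ankle": ankle, "knee": knee, "speed": speed}[what]
        out[m] = np.interp(phase, pattern.pct, src)
    return out


def make_trial(profile: ParticipantProfile, pattern: GaitPattern,
               spec: TrialSpec, fs: float = IMU_FS,
               tap_interval: float = DEFAULT_TAP_INTERVAL) -> SyntheticTrial:
    """Generate one walking trial: kinematics + wave-speed truth + stream.

    The wave-speed stream is reported on the tensiometry clock, which
    starts ``spec.sync_delay`` seconds AFTER the kinematic clock (the
    wireless trigger latency): a physical event at kinematic time ``t``
    appears at tensiometry time ``t - sync_delay``.  The truth dict
    carries heel-strike times, per-stride slopes/lengths/times, the
    wave-speed truth on the kinematic clock, and ``expected_offset``
    (= -sync_delay), the lag the sync stage should estimate.
    """
    rng = np.random.default_rng(spec.seed)
    starts, stride_times, stride_lengths = _phase_arrays(spec, profile, pattern)
    duration = float(starts[-1] + stride_times[-1])
    slopes = spec.slope_sequence
    # short hold after the last stride so the final heel strike is
    # detectable and the wave-speed stream covers the last stride
    tail = 0.3

    t_kin = np.arange(0.0, duration + tail, 1.0 / fs)
    ankle = _eval_gait(t_kin, starts, stride_times, slopes, pattern, "ankle")
    knee = _eval_gait(t_kin, starts, stride_times, slopes, pattern, "knee")
    # pelvis advances proportionally to gait phase within each stride
    edges = np.concatenate([starts, [duration]])
    idx = np.clip(np.searchsorted(edges, t_kin, side="right") - 1, 0,
                  len(starts) - 1)
    x_start = np.concatenate([[0.0], np.cumsum(stride_lengths)[:-1]])
    phase = (t_kin - starts[idx]) / stride_times[idx]
    pelvis = x_start[idx] + np.clip(phase, 0, 1) * stride_lengths[idx]

    if spec.noise_scale > 0:
        ankle = ankle + rng.normal(0.0, spec.noise_scale * np.ptp(ankle), ankle.size)
        knee = knee + rng.normal(0.0, spec.noise_scale * np.ptp(knee), knee.size)

    # heel-strike impact channel: decaying 25 Hz burst at each stride
    # boundary (including the final one, inside the tail)
    foot = rng.normal(0.0, 0.05, t_kin.size)
    for t0 in np.append(starts, duration):
        seg = (t_kin >= t0) & (t_kin < t0 + 0.12)
        tau = t_kin[seg] - t0
        foot[seg] += np.exp(-tau / 0.03) * np.sin(2 * np.pi * 25.0 * tau)

    # wave-speed truth at tap cadence on the kinematic clock
    t_tap = np.arange(tap_interval, duration + tail - tap_interval,
                      tap_interval)
    s_true = _eval_gait(t_tap, starts, stride_times, slopes, pattern, "speed")
    # the generator's load truth is the moment template run through the
    # participant's own calibration: reject profiles whose floor is violated
    m_true = MEAN_C1 * s_true**2 + MEAN_C0
    s2 = (m_true - profile.calib_intercept) / profile.calib_slope
    if np.any(s2 <= 0):
        raise ValueError(
            f"moment template reaches {m_true.min():.2f} N*m, below participant "
            f"{profile.id} calibration floor c0={profile.calib_intercept:.2f}")
    s_part = np.sqrt(s2)

    s_noisy = s_part.copy()
    if spec.noise_scale > 0:
        s_noisy = s_noisy + rng.normal(0.0, spec.noise_scale * np.ptp(s_part),
                                       s_part.size)
    # tensiometry clock: starts sync_delay late
    stream = WaveSpeedSeries(times=t_tap - spec.sync_delay, speeds=s_noisy)

    kin = JointKinematicsSeries(times=t_kin, ankle_deg=ankle, knee_deg=knee,
                                pelvis_x=pelvis, fs=fs, foot_accel=foot)
    truth = {
        "heel_strikes": np.append(starts, duration),
        "stride_times": stride_times,
        "stride_lengths": stride_lengths,
        "slopes": slopes,
        "wave_speed_times": t_tap,
        "wave_speeds": s_part,
        "moment": m_true,
        "sync_delay": spec.sync_delay,
        "expected_offset": -spec.sync_delay,
    }
    return SyntheticTrial(kinematics=kin, wave_speed_stream=stream, truth=truth)


# ---------------------------------------------------------------------------
# raw tap-recording rendering

TAP_BURST_DURATION = 0.002   # s
TAP_BURST_CARRIER = 800.0    # Hz, inside the 150-1500 Hz analysis band
CH2_ATTENUATION = 0.5


def tap_wavelet(t: np.ndarray, duration: float = TAP_BURST_DURATION,
                carrier: float = TAP_BURST_CARRIER) -> np.ndarray:
    """Raised-cosine windowed sine burst, nonzero on [0, duration]."""
    t = np.asarray(t, dtype=float)
    w = np.zeros_like(t)
    m = (t >= 0.0) & (t <= duration)
    w[m] = 0.5 * (1.0 - np.cos(2 * np.pi * t[m] / duration)) \
        * np.sin(2 * np.pi * carrier * t[m])
    return w


def render_tap_recording(wave_speed_truth: WaveSpeedSeries,
                         fs: float = DEFAULT_FS,
                         spacing: float = DEFAULT_SPACING,
                         tap_interval: float = DEFAULT_TAP_INTERVAL,
                         noise_scale: float = 1.6e-5,
                         seed: int = 0,
                         attenuation: float = CH2_ATTENUATION) -> AccelRecording:
    """Render a two-channel raw recording from a wave-speed truth series.

    Channel 1 carries a tap burst every ``tap_interval`` seconds; channel 2
    carries the same burst delayed by ``spacing / S(t)`` (the shear-wave
    travel time at that tap), attenuated, and with twice the additive
    noise.  Subsample delays are exact: the analytic burst waveform is
    evaluated at the delayed sample times.  ``noise_scale`` is the additive
    noise standard deviation as a fraction of the channel-1 peak amplitude
    (accelerometer noise floors span roughly 1e-6 to 3.2e-5 of the signal).
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    rng = np.random.default_rng(seed)
    t0 = float(wave_speed_truth.times[0])
    t1 = float(wave_speed_truth.times[-1])
    # pre-roll half a tap interval so the first burst is not clipped at
    # the array edge (which would bias its correlation window)
    start = t0 - tap_interval / 2.0
    n = int(np.ceil((t1 - start + 2 * tap_interval) * fs))
    ch1 = np.zeros(n)
    ch2 = np.zeros(n)
    tap_times = np.arange(t0, t1, tap_interval)
    speeds = np.interp(tap_times, wave_speed_truth.times, wave_speed_truth.speeds)
    nwin = int(np.ceil((TAP_BURST_DURATION + spacing / 2.0) * fs)) + 2
    for tk, sk in zip(tap_times, speeds):
        delay = spacing / sk
        i0 = int(np.floor((tk - start) * fs))
        i1 = min(i0 + nwin, n)
        ts = start + np.arange(i0, i1) / fs
        ch1[i0:i1] += tap_wavelet(ts - tk)
        ch2[i0:i1] += attenuation * tap_wavelet(ts - tk - delay)
    if noise_scale > 0:
        amp = np.abs(ch1).max()
        ch1 += rng.normal(0.0, noise_scale * amp, n)
        ch2 += rng.normal(0.0, 2.0 * noise_scale * amp, n)
    return AccelRecording(ch1=ch1, ch2=ch2, fs=fs, start_time=start)


# ---------------------------------------------------------------------------
# course generation

def make_course(total_length: float = 800.0, max_slope: float = 10.0,
                section_length: float = 50.0, seed: int = 0,
                grid_step: float = 0.5,
                blend_length: float = 5.0) -> tuple[CourseMap, dict]:
    """Out-and-back course with a piecewise-smooth incline profile.

    The outward half (``total_length / 2``) is divided into sections of
    ``section_length`` with sampled inclines; section inclines are chosen
    so that every 2-degree bin magnitude up to ``max_slope`` is covered
    (sign is irrelevant: the return pass mirrors the profile with flipped
    sign, so incline at position p equals minus the incline at the
    mirrored position).  Transitions between sections are smoothstep
    blends over ``blend_length`` meters.

    Returns the ground-truth :class:`CourseMap` over the full out-and-back
    displacement axis and a truth dict with the section table.
    """
    if total_length <= 0 or section_length <= 0:
        raise ValueError("lengths must be positive")
    if abs(max_slope) > 10.0:
        raise ValueError("|max_slope| must be at most 10 degrees")
    rng = np.random.default_rng(seed)
    half = total_length / 2.0
    n_sections = max(int(np.round(half / section_length)), 1)
    # guarantee bin coverage: one section per even-degree magnitude first
    magnitudes = np.arange(0.0, max_slope + 1e-9, 2.0)
    incs = []
    for m in magnitudes[:n_sections]:
        incs.append(m * rng.choice([-1.0, 1.0]) if m > 0 else 0.0)
    while len(incs) < n_sections:
        incs.append(rng.uniform(-max_slope, max_slope))
    incs = np.array(incs)
    rng.shuffle(incs)
    if max_slope == 0:
        incs[:] = 0.0

    grid = np.arange(0.0, total_length + grid_step / 2.0, grid_step)
    out_profile = np.zeros_like(grid)
    half_mask = grid <= half
    g = grid[half_mask]
    section_idx = np.clip((g // section_length).astype(int), 0, n_sections - 1)
    prof = incs[section_idx].astype(float)
    # smoothstep blending across section boundaries
    for b in np.arange(section_length, half, section_length):
        j = int(np.searchsorted(g, b))
        left = incs[min(int(b // section_length) - 1, n_sections - 1)]
        right = incs[min(int(b // section_length), n_sections - 1)]
        m = np.abs(g - b) <= blend_length / 2.0
        u = (g[m] - (b - blend_length / 2.0)) / blend_length
        prof[m] = left + (right - left) * (3 * u**2 - 2 * u**3)
    out_profile[half_mask] = prof
    # mirror with sign flip onto the return half
    back = ~half_mask
    out_profile[back] = -np.interp(total_length - grid[back], g, prof)
    truth = {"section_inclines": incs, "section_length": section_length,
             "half_length": half}
    return CourseMap(positions=grid, inclines=out_profile), truth


# ---------------------------------------------------------------------------
# sway (calibration) trials

@dataclass
class SwayTrial:
    """Balance-plate sway trial plus the tensiometer-side streams."""

    Fz: np.ndarray             # N, plate clock
    COP_ap: np.ndarray         # m, plate clock
    ankle_axis_ap: float       # m
    accel_stream: np.ndarray   # impact-bearing stream, tensiometer clock
    wave_speed: WaveSpeedSeries  # tensiometer clock
    fs: float
    truth: dict


def make_sway_trial(profile: ParticipantProfile, duration: float = 30.0,
                    impact_time: float = 0.35, noise_scale: float = 0.0,
                    seed: int = 0, fs: float = 1000.0,
                    sync_offset: float = 0.0) -> SwayTrial:
    """Anterior-posterior sway on a balance plate, with an alignment spike.

    The center of pressure oscillates anterior of the ankle axis; the net
    ankle moment is ``Fz * (COP - axis)`` and the wave-speed truth is that
    moment run through the participant's inverse calibration.  A sharp
    manual-strike spike is injected at ``impact_time`` (plate clock) in
    both the vertical force and the tensiometer-side accel stream; the
    tensiometer streams run ``sync_offset`` seconds behind the plate
    clock.
    """
    if not (0.0 < impact_time < duration):
        raise ValueError("impact_time must lie inside the trial")
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / fs)
    axis = 0.08  # m, malleolar axis in the plate frame
    cop = axis + 0.042 + 0.036 * np.sin(2 * np.pi * 0.25 * t) \
        + 0.010 * np.sin(2 * np.pi * 0.11 * t)
    g = 9.81
    fz = profile.mass * g * (1.0 + 0.02 * np.sin(2 * np.pi * 0.5 * t))
    if noise_scale > 0:
        cop = cop + rng.normal(0.0, noise_scale * np.ptp(cop), t.size)
        fz = fz + rng.normal(0.0, noise_scale * np.ptp(fz), t.size)
        fz = np.maximum(fz, 0.0)
    moment = fz * (cop - axis)
    s2 = (moment - profile.calib_intercept) / profile.calib_slope
    if np.any(s2 <= 0):
        raise ValueError("sway moment fell below the calibration floor")
    speeds = np.sqrt(s2)
    if noise_scale > 0:
        speeds = np.abs(speeds + rng.normal(0.0, noise_scale * np.ptp(speeds),
                                            t.size))
    # manual strike: sharp decaying spike, onset exactly at impact_time
    def _spike(onset, amp):
        m = (t >= onset) & (t < onset + 0.01)
        out = np.zeros_like(t)
        out[m] = amp * np.exp(-(t[m] - onset) / 0.002)
        return out

    fz_spiked = fz + _spike(impact_time, 2.0 * profile.mass * g)
    accel = rng.normal(0.0, 0.02, t.size) \
        + _spike(impact_time - sync_offset, 5.0)
    ws = WaveSpeedSeries(times=t - sync_offset, speeds=speeds)
    truth = {"c1": profile.calib_slope, "c0": profile.calib_intercept,
             "sync_offset": sync_offset, "impact_time": impact_time,
             "moment": moment}
    return SwayTrial(Fz=fz_spiked, COP_ap=cop, ankle_axis_ap=axis,
                     accel_stream=accel, wave_speed=ws, fs=fs, truth=truth)


# ---------------------------------------------------------------------------
# cohort work set

#: slope-sensitivity defaults, J/kg per degree (piecewise, knot at 0 deg)
SOLEUS_SENS_DECLINE = 0.02
SOLEUS_SENS_INCLINE = 0.01
GASTROC_SENS_DECLINE = 0.008
GASTROC_SENS_INCLINE = -0.008
WORK_NOISE_SD = 0.05        # J/kg
WORKSET_FS = 500.0          # Hz of the emitted force/velocity streams
SOLEUS_LEVEL_WORK = 0.25    # J/kg, cohort-mean level net soleus work
GASTROC_LEVEL_WORK = 0.10   # J/kg


@dataclass
class WorksetStride:
    """One stride's emitted force/velocity streams for both muscles."""

    participant_id: str
    slope: float                 # degrees
    times: np.ndarray            # s
    FS: np.ndarray               # N/kg
    VS: np.ndarray               # m/s
    FG: np.ndarray               # N/kg
    VG: np.ndarray               # m/s


@dataclass
class CohortWorkset:
    """Synthetic cohort of strides with known per-stride net work."""

    strides: list
    truth: "object"  # pandas DataFrame: participant_id, slope, WS_true, WG_true


def _hann_bump(u, lo, hi):
    out = np.zeros_like(u)
    m = (u >= lo) & (u <= hi)
    out[m] = 0.5 * (1.0 - np.cos(2 * np.pi * (u[m] - lo) / (hi - lo)))
    return out


def _power_profile(u: np.ndarray) -> np.ndarray:
    """Unit power template over normalized stride time u in [0, 1].

    A negative early-stance absorption phase followed by a positive
    push-off burst; the analytic net integral over u is
    ``-0.3 * 0.30 / 2 + 1.0 * 0.20 / 2 = 0.055`` (bump integral is
    amplitude * width / 2).
    """
    return -0.3 * _hann_bump(u, 0.05, 0.35) + 1.0 * _hann_bump(u, 0.40, 0.60)


_UNIT_NET = -0.3 * 0.30 / 2.0 + 1.0 * 0.20 / 2.0  # analytic ∫ over u


def piecewise_work_truth(slope, w_level, sens_decline, sens_incline):
    """Intended net work: piecewise-linear in slope with a knot at 0 deg."""
    s = np.asarray(slope, dtype=float)
    return w_level + np.where(s < 0, sens_decline * s, sens_incline * s)


def make_cohort_workset(n_participants: int = 11, strides_per: int = 200,
                        soleus_sens_decline: float = SOLEUS_SENS_DECLINE,
                        soleus_sens_incline: float = SOLEUS_SENS_INCLINE,
                        gastroc_sens_decline: float = GASTROC_SENS_DECLINE,
                        gastroc_sens_incline: float = GASTROC_SENS_INCLINE,
                        work_noise_sd: float = WORK_NOISE_SD,
                        seed: int = 0,
                        stride_time: float = 1.22,
                        fs: float = WORKSET_FS,
                        level_work_sd: tuple = (0.05, 0.03)) -> CohortWorkset:
    """Cohort of strides whose true net work follows a piecewise slope law.

    For every stride a power-profile template is scaled so its exact time
    integral equals ``W_level + sens * slope + N(0, work_noise_sd)`` (sens
    switching at 0 degrees), then factored into a strictly positive force
    stream and the matching velocity stream (``P = -F * V``) so the
    downstream work integrator is exercised end to end.  Participant-level
    level-work offsets are drawn once per participant, which the
    zero-referencing stage must remove.
    """
    if strides_per < 20:
        raise ValueError("strides_per must be at least 20")
    if n_participants < 1:
        raise ValueError("need at least one participant")
    import pandas as pd
    rng = np.random.default_rng(seed)
    n = int(round(stride_time * fs)) + 1
    t = np.linspace(0.0, stride_time, n)
    u = t / stride_time
    p0 = _power_profile(u)
    net0 = _UNIT_NET * stride_time      # analytic ∫ p0 dt
    force = 2.0 + 8.0 * _hann_bump(u, 0.10, 0.70)   # N/kg, strictly positive
    # cyclic correction basis: g has zero force-weighted integral, so adding
    # alpha * g to a velocity stream leaves stride work unchanged while
    # zeroing the net excursion (MTU length returns to its start over a
    # stride, as in steady gait)
    from scipy.integrate import trapezoid
    c_star = trapezoid(force**2, t) / trapezoid(force, t)
    g_basis = c_star - force
    g_int = trapezoid(g_basis, t)

    def _velocity(power):
        v = -power / force
        return v - (trapezoid(v, t) / g_int) * g_basis

    strides, rows = [], []
    for ip in range(n_participants):
        pid = f"P{ip:02d}"
        w_level_s = SOLEUS_LEVEL_WORK + rng.normal(0.0, level_work_sd[0])
        w_level_g = GASTROC_LEVEL_WORK + rng.normal(0.0, level_work_sd[1])
        slopes = rng.uniform(-10.0, 10.0, strides_per)
        for s in slopes:
            ws = float(piecewise_work_truth(s, w_level_s,
                                            soleus_sens_decline,
                                            soleus_sens_incline)
                       + rng.normal(0.0, work_noise_sd))
            wg = float(piecewise_work_truth(s, w_level_g,
                                            gastroc_sens_decline,
                                            gastroc_sens_incline)
                       + rng.normal(0.0, work_noise_sd))
            ps = p0 * (ws / net0)
            pg = p0 * (wg / net0)
            strides.append(WorksetStride(
                participant_id=pid, slope=float(s), times=t,
                FS=force, VS=_velocity(ps), FG=force, VG=_velocity(pg)))
            rows.append({"participant_id": pid, "slope": float(s),
                         "WS_true": ws, "WG_true": wg})
    return CohortWorkset(strides=strides, truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cohort profile sampling

def make_cohort_profiles(n: int = 11, seed: int = 0) -> list[ParticipantProfile]:
    """Participant profiles with cohort-level spread around the study means."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        profiles.append(ParticipantProfile(
            id=f"P{i:02d}",
            mass=float(np.clip(rng.normal(76.5, 13.6), 45.0, 120.0)),
            calib_slope=float(np.clip(rng.normal(MEAN_C1, 0.008), 0.02, 0.10)),
            calib_intercept=float(rng.normal(MEAN_C0, 3.0)),
            level_stride_length=float(np.clip(rng.normal(LEVEL_STRIDE_LENGTH,
                                                         0.25), 0.8, 2.5)),
            level_speed=float(np.clip(rng.normal(LEVEL_SPEED, 0.10), 0.8, 2.0)),
        ))
    return profiles
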