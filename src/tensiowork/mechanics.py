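"""Triceps surae muscle-tendon mechanics.

Moment arms, muscle-tendon-unit (MTU) velocities and excursions, force
apportionment, power, stride work, work against gravity and work loops.

Conventions
-----------
* Ankle dorsiflexion angle ``theta`` and knee flexion angle ``phi`` are in
  degrees, zero at a straight-legged upright neutral pose.  Dorsiflexion
  and knee extension lengthen the plantarflexor MTUs.
* Moment-arm polynomials take DEGREES and return METERS.  Angular
  velocities multiplying a moment arm must be in RAD/S so that MTU
  velocities come out in m/s; this is the only dimensionally consistent
  reading and is enforced by the API (arguments are named ``*_radps``).
  The same pi/180 factor appears in the excursion integrals.
* Positive MTU velocity = lengthening.  Power is the NEGATIVE product of
  force and lengthening velocity, so a muscle shortening under tension
  produces positive power.
* Forces are apportioned 65% soleus / 35% gastrocnemius, the ratio of
  physiological cross-sectional areas, and normalized to body mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

DEG = np.pi / 180.0
GRAVITY = 9.81  # m/s^2
SOLEUS_FRACTION = 0.65


@dataclass(frozen=True)
class MomentArmModel:
    """Quadratic joint-angle -> moment-arm maps (degrees -> m).

    ``ankle_coeffs`` (a2, a1, a0) give the Achilles tendon moment arm about
    the ankle as a function of dorsiflexion; ``knee_coeffs`` (b2, b1, b0)
    give the proximal gastrocnemius tendon moment arm about the knee as a
    function of knee flexion.  Defaults are generic healthy-young-adult
    fits.
    """

    ankle_coeffs: tuple[float, float, float] = (1.4e-6, -1.7e-4, 4.4e-2)
    knee_coeffs: tuple[float, float, float] = (-2.0e-6, 3.8e-4, 1.8e-2)

    def r_ankle(self, theta_deg):
        a2, a1, a0 = self.ankle_coeffs
        th = np.asarray(theta_deg, dtype=float)
        return a2 * th**2 + a1 * th + a0

    def r_knee(self, phi_deg):
        b2, b1, b0 = self.knee_coeffs
        ph = np.asarray(phi_deg, dtype=float)
        return b2 * ph**2 + b1 * ph + b0


def moment_arms(theta_deg, phi_deg, model: MomentArmModel | None = None):
    """(R_ankle, R_knee) in meters at the given joint angles in degrees."""
    model = model or MomentArmModel()
    return model.r_ankle(theta_deg), model.r_knee(phi_deg)


def mtu_velocities(theta_deg, theta_dot_radps, phi_deg, phi_dot_radps,
                   model: MomentArmModel | None = None):
    """Soleus and gastrocnemius MTU lengthening velocities, m/s.

    ``VS = R_ankle(theta) * theta_dot``;
    ``VG = R_ankle(theta) * theta_dot - R_knee(phi) * phi_dot``
    (the gastrocnemius is biarticular: knee flexion shortens it).
    Angular velocities must be in rad/s.
    """
    model = model or MomentArmModel()
    vs = model.r_ankle(theta_deg) * np.asarray(theta_dot_radps, dtype=float)
    vg = vs - model.r_knee(phi_deg) * np.asarray(phi_dot_radps, dtype=float)
    return vs, vg


def _poly_excursion(coeffs, angle_deg):
    # closed-form integral of the quadratic moment arm over angle, with the
    # deg->rad factor so the result is meters of MTU length change
    c2, c1, c0 = coeffs
    a = np.asarray(angle_deg, dtype=float)
    return DEG * (c2 * a**3 / 3.0 + c1 * a**2 / 2.0 + c0 * a)


def mtu_excursions(theta_deg, phi_deg, model: MomentArmModel | None = None):
    """MTU length change (m) relative to the neutral upright pose.

    Symbolic integral of the moment-arm polynomials with respect to joint
    angle (in radians, hence the pi/180 factor): dorsiflexion lengthens
    both MTUs through the ankle term; knee flexion shortens the
    gastrocnemius through the knee term.  Zero at ``theta = phi = 0``.
    """
    model = model or MomentArmModel()
    dl_ankle = _poly_excursion(model.ankle_coeffs, theta_deg)
    dl_s = dl_ankle
    dl_g = dl_ankle - _poly_excursion(model.knee_coeffs, phi_deg)
    return dl_s, dl_g


def tendon_force_and_apportion(M, theta_deg, mass: float,
                               soleus_frac: float = SOLEUS_FRACTION,
                               model: MomentArmModel | None = None):
    """Total Achilles force and its mass-normalized soleus/gastroc shares.

    ``F = M / R_ankle(theta)`` (N); ``FS = soleus_frac * F / mass`` and
    ``FG = (1 - soleus_frac) * F / mass`` (N/kg).  Negative moments are
    clipped to zero force — a tendon transmits tension only — and the
    number of clipped samples is logged.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    model = model or MomentArmModel()
    M = np.asarray(M, dtype=float)
    r = model.r_ankle(theta_deg)
    if np.any(r <= 0):
        raise ValueError("ankle moment arm must be positive over the input range")
    n_clipped = int(np.sum(M < 0))
    if n_clipped:
        log.info("tendon_force_and_apportion: clipped %d negative-moment samples",
                 n_clipped)
    F = np.maximum(M, 0.0) / r
    FS = soleus_frac * F / mass
    FG = (1.0 - soleus_frac) * F / mass
    return F, FS, FG


def mtu_power(F_muscle, V_muscle):
    """Mass-normalized MTU power, W/kg: ``P = -V * F``.

    Shortening (V < 0) under tension gives positive power; lengthening
    under tension absorbs energy (negative power).
    """
    return -np.asarray(V_muscle, dtype=float) * np.asarray(F_muscle, dtype=float)


def stride_work(P, times) -> tuple[float, float, float]:
    """Trapezoidal net / positive / negative work over one stride, J/kg.

    Positive work integrates ``max(P, 0)``, negative work ``min(P, 0)``;
    net = pos + neg by linearity of the trapezoid rule.
    """
    P = np.asarray(P, dtype=float)
    t = np.asarray(times, dtype=float)
    if P.size < 2:
        raise ValueError("need at least two samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    pos = float(np.trapezoid(np.maximum(P, 0.0), t))
    neg = float(np.trapezoid(np.minimum(P, 0.0), t))
    return pos + neg, pos, neg


def work_against_gravity(stride_length: float, slope_deg: float,
                         g: float = GRAVITY) -> float:
    """Mass-normalized work against gravity per step, J/kg.

    Half the product of gravitational weight (per kg), stride length and
    the tangent of the terrain incline: each step raises the body by half
    the stride's elevation gain.
    """
    if abs(slope_deg) >= 90:
        raise ValueError("slope must be within (-90, 90) degrees")
    return 0.5 * g * stride_length * np.tan(slope_deg * DEG)


def work_loop(force, excursion, heel_strike_index: int = 0):
    """Closed force-excursion path and its signed (shoelace) area.

    The path starts at heel strike, follows the stride in time order and
    closes back to the start.  The signed area (positive for
    counter-clockwise progression in the excursion-force plane) equals the
    net work of the stride: dW = -F dL, and the shoelace sum of the closed
    loop evaluates exactly that line integral.

    Returns ``(path, area)`` where path is an (n+1, 2) array of
    (excursion, force) vertices with the first vertex repeated at the end.
    """
    F = np.asarray(force, dtype=float)
    L = np.asarray(excursion, dtype=float)
    if F.size != L.size:
        raise ValueError("force and excursion must have equal length")
    if F.size < 3:
        raise ValueError("work loop needs at least 3 samples")
    order = np.r_[np.arange(heel_strike_index, F.size),
                  np.arange(0, heel_strike_index)]
    x = L[order]
    y = F[order]
    xc = np.r_[x, x[0]]
    yc = np.r_[y, y[0]]
    area = 0.5 * float(np.sum(xc[:-1] * yc[1:] - xc[1:] * yc[:-1]))
    return np.column_stack([xc, yc]), area


@dataclass
class MTUStrideMechanics:
    """Per-sample mechanics of one stride for both triceps surae units."""

    times: np.ndarray            # s
    VS: np.ndarray               # m/s
    VG: np.ndarray               # m/s
    excursion_S: np.ndarray      # m
    excursion_G: np.ndarray      # m
    FS: np.ndarray               # N/kg
    FG: np.ndarray               # N/kg
    PS: np.ndarray               # W/kg
    PG: np.ndarray               # W/kg

    def work_summary(self, stride_length: float = np.nan,
                     slope_deg: float = np.nan) -> "WorkSummary":
        ws_net, ws_pos, ws_neg = stride_work(self.PS, self.times)
        wg_net, wg_pos, wg_neg = stride_work(self.PG, self.times)
        w_grav = (work_against_gravity(stride_length, slope_deg)
                  if np.isfinite(stride_length) and np.isfinite(slope_deg) else np.nan)
        return WorkSummary(WS_net=ws_net, WS_pos=ws_pos, WS_neg=ws_neg,
                           WG_net=wg_net, WG_pos=wg_pos, WG_neg=wg_neg,
                           W_gravity=w_grav)


@dataclass
class WorkSummary:
    """Integrated stride work per muscle (J/kg) plus work against gravity."""

    WS_net: float
    WS_pos: float
    WS_neg: float
    WG_net: float
    WG_pos: float
    WG_neg: float
    W_gravity: float = np.nan


def smooth_and_differentiate(angles_deg, fs: float, cutoff: float = 6.0):
    """Angular velocity (rad/s) from a sampled joint-angle stream (degrees).

    The stream is low-pass filtered (zero-phase 4th-order Butterworth,
    default 6 Hz — gait kinematics carry little power above that) and
    differentiated by central differences.  Returns the smoothed angles
    (degrees) and the angular velocity in rad/s.
    """
    from scipy import signal as sps
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 15 or cutoff >= fs / 2:
        smoothed = a
    else:
        sos = sps.butter(4, cutoff, btype="low", fs=fs, output="sos")
        smoothed = sps.sosfiltfilt(sos, a)
    vel = np.gradient(smoothed, 1.0 / fs) * DEG
    return smoothed, vel


def stride_mechanics(times, theta_deg, phi_deg, wave_speeds, mass: float,
                     calibration=None, model: MomentArmModel | None = None,
                     fs: float | None = None,
                     soleus_frac: float = SOLEUS_FRACTION) -> MTUStrideMechanics:
    """Assemble full per-sample mechanics for one stride.

    Inputs are the stride's joint-angle streams (degrees), the wave-speed
    stream resampled onto the same time grid (m/s), and body mass (kg).
    Wave speed is converted to moment through the participant calibration,
    then to apportioned forces, velocities, excursions and powers.
    """
    from .calibration import CalibrationModel, moment_from_wave_speed
    calibration = calibration or CalibrationModel()
    model = model or MomentArmModel()
    t = np.asarray(times, dtype=float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    theta_s, theta_dot = smooth_and_differentiate(theta_deg, fs)
    phi_s, phi_dot = smooth_and_differentiate(phi_deg, fs)
    M = moment_from_wave_speed(wave_speeds, calibration)
    _, FS, FG = tendon_force_and_apportion(M, theta_s, mass,
                                           soleus_frac=soleus_frac, model=model)
    VS, VG = mtu_velocities(theta_s, theta_dot, phi_s, phi_dot, model=model)
    exc_s, exc_g = mtu_excursions(theta_s, phi_s, model=model)
    return MTUStrideMechanics(times=t, VS=VS, VG=VG,
                              excursion_S=exc_s, excursion_G=exc_g,
                              FS=FS, FG=FG,
                              PS=mtu_power(FS, VS), PG=mtu_power(FG, VG))
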