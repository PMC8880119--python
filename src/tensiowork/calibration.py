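"""Participant-specific tendon load calibration.

A tensioned-beam model predicts that tendon tension — and hence the net
ankle plantarflexion moment it produces — scales linearly with squared
shear-wave speed.  Each participant performs a standing anterior-posterior
sway trial on a balance plate: vertical ground reaction force and center
of pressure (1000 Hz) give the net ankle moment, the tensiometer gives the
wave speed, and an ordinary least-squares fit of moment on squared speed
yields the per-participant calibration ``M = c1 * S**2 + c0``.  The cohort
mean fit is ``M = 0.05 S^2 - 17.0`` (N*m with S in m/s), which serves as
the default model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm

#: cohort-mean calibration coefficients (N*m per (m/s)^2, N*m)
MEAN_C1 = 0.05
MEAN_C0 = -17.0


@dataclass
class BalancePlateRecording:
    """Vertical force and anterior-posterior center of pressure at 1000 Hz."""

    Fz: np.ndarray          # N
    COP_ap: np.ndarray      # m, plate frame
    ankle_axis_ap: float    # m, A-P location of the ankle (malleolar) axis
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.Fz = np.asarray(self.Fz, dtype=float)
        self.COP_ap = np.asarray(self.COP_ap, dtype=float)
        if self.Fz.shape != self.COP_ap.shape:
            raise ValueError("Fz and COP streams must have equal length")
        if np.any(self.Fz < 0):
            raise ValueError("vertical force must be non-negative")


@dataclass
class CalibrationModel:
    """Linear map between squared wave speed and net ankle moment."""

    c1: float = MEAN_C1      # N*m per (m/s)^2
    c0: float = MEAN_C0      # N*m; -c0/c1 is the squared unloaded wave speed
    r_squared: float = 1.0
    participant_id: str = "mean"

    def __post_init__(self) -> None:
        if self.c1 <= 0:
            raise ValueError("c1 must be positive (moment increases with wave speed)")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        return cls(**json.loads(text))


def moment_from_wave_speed(S, model: CalibrationModel | None = None):
    """Net ankle moment (N*m) from shear-wave speed (m/s): ``M = c1 S^2 + c0``."""
    model = model or CalibrationModel()
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("wave speed must be non-negative")
    return model.c1 * S**2 + model.c0


def wave_speed_from_moment(M, model: CalibrationModel | None = None):
    """Inverse calibration: ``S = sqrt((M - c0) / c1)``.

    Rejects moments below the calibration floor ``c0`` (which would imply a
    negative squared speed and an unphysical, slack-beyond-model tendon).
    """
    model = model or CalibrationModel()
    M = np.asarray(M, dtype=float)
    s2 = (M - model.c0) / model.c1
    if np.any(s2 < 0):
        bad = float(np.min(M))
        raise ValueError(
            f"moment {bad:.3f} N*m below calibration intercept floor c0={model.c0:.3f};"
            " squared wave speed would be negative")
    return np.sqrt(s2)


def ankle_moment_from_plate(plate: BalancePlateRecording) -> np.ndarray:
    """Net ankle moment stream M(t) = Fz(t) * (COP_ap(t) - ankle_axis_ap)."""
    return plate.Fz * (plate.COP_ap - plate.ankle_axis_ap)


def align_plate_to_accel(plate_sig: np.ndarray, accel_sig: np.ndarray,
                         fs: float = 1000.0, spike_mads: float = 5.0) -> float:
    """Clock offset between plate and tensiometer streams from a shared impact.

    The plate is struck once, producing a sharp spike in both the vertical
    force and the accelerometer-derived stream.  Both signals must show a
    spike exceeding ``spike_mads`` times their MAD; the offset (seconds to
    add to the accel clock so it matches the plate clock) is the lag
    maximizing the cross-correlation of the mean-removed streams.
    """
    a = np.asarray(plate_sig, dtype=float)
    b = np.asarray(accel_sig, dtype=float)
    for name, x in (("plate", a), ("accel", b)):
        dev = np.abs(x - np.median(x))
        mad = np.median(dev) + 1e-300
        if dev.max() < spike_mads * mad:
            raise ValueError(f"no impact spike in {name} stream "
                             f"(max deviation {dev.max() / mad:.1f} MADs)")
    a = a - a.mean()
    b = b - b.mean()
    n = min(a.size, b.size)
    from scipy.signal import correlate
    c = correlate(a[:n], b[:n], mode="full")
    lag = int(np.argmax(c)) - (n - 1)
    return lag / fs


def fit_calibration(S: np.ndarray, M: np.ndarray,
                    participant_id: str = "unknown",
                    min_samples: int = 100) -> CalibrationModel:
    """OLS fit of ankle moment on squared wave speed.

    ``S`` and ``M`` must already share a clock and sample grid.  Requires a
    non-degenerate design (wave speed must actually vary during the sway).
    """
    S = np.asarray(S, dtype=float)
    M = np.asarray(M, dtype=float)
    if S.size != M.size:
        raise ValueError("streams must be paired")
    if S.size < min_samples:
        raise ValueError(f"need at least {min_samples} paired samples, got {S.size}")
    s2 = S**2
    if np.var(s2) < 1e-12 * max(1.0, np.mean(s2) ** 2):
        raise ValueError("degenerate design: squared wave speed is (near-)constant")
    res = sm.OLS(M, sm.add_constant(s2)).fit()
    c0, c1 = res.params
    return CalibrationModel(c1=float(c1), c0=float(c0),
                            r_squared=float(min(max(res.rsquared, 0.0), 1.0)),
                            participant_id=participant_id)


def compare_calibrations(pre: CalibrationModel, post: CalibrationModel,
                         drift_threshold: float = 0.15) -> dict:
    """Relative coefficient drift between session-start and session-end fits.

    Returns ``{"dc1_rel", "dc0", "dc0_rel", "drift"}``; ``drift`` is set
    when either relative change exceeds ``drift_threshold`` (default 15%).
    """
    dc1_rel = (post.c1 - pre.c1) / pre.c1
    dc0 = post.c0 - pre.c0
    dc0_rel = dc0 / abs(pre.c0) if pre.c0 != 0 else np.inf * np.sign(dc0) if dc0 else 0.0
    drift = bool(abs(dc1_rel) > drift_threshold or abs(dc0_rel) > drift_threshold)
    return {"dc1_rel": float(dc1_rel), "dc0": float(dc0),
            "dc0_rel": float(dc0_rel), "drift": drift}
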