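"""Inter-system start-delay estimation and correction.

The kinematic (IMU) and tensiometry recorders are started by a wireless
trigger with non-deterministic latency (up to ~100 ms), so the two
streams share a clock only approximately.  During early stance the ankle
flexion angle and the tendon wave speed rise together; cross-correlating
the two over the first 10% of the gait cycle of level strides therefore
recovers the start offset, which is then removed from the whole trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: lag search bound, s (trigger latency is at most ~0.1 s; margin for noise)
MAX_LAG = 0.15
#: internal resampling rate for lag search, Hz
RESAMPLE_FS = 1000.0


@dataclass
class SyncEstimate:
    """Per-stride lags and their mean, the applied trial offset."""

    per_stride_lags: np.ndarray   # s
    mean_offset: float            # s
    n_strides_used: int

    def __post_init__(self) -> None:
        self.per_stride_lags = np.asarray(self.per_stride_lags, dtype=float)
        if self.n_strides_used < 1:
            raise ValueError("at least one stride required")
        if not (-MAX_LAG <= self.mean_offset <= MAX_LAG):
            raise ValueError("mean offset outside the physical search range")


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else x - x.mean()


def _stride_lag(kin_t, kin_angle, ws_t, ws_speed, t0: float, t1: float,
                window_fraction: float, max_lag: float, fs: float) -> float:
    """Lag (s) of the wave-speed stream relative to the kinematic stream.

    The first ``window_fraction`` of the stride [t0, t1] of the ankle angle
    is compared against the wave-speed stream shifted by each candidate
    lag; each comparison is a per-lag-normalized correlation of z-scored
    windows, so the argmax is the lag at which the two shapes best match.
    """
    t_end = t0 + window_fraction * (t1 - t0)
    grid = np.arange(t0, t_end, 1.0 / fs)
    if grid.size < 8:
        return np.nan
    ang = _zscore(np.interp(grid, kin_t, kin_angle))
    lags = np.arange(-max_lag, max_lag + 0.5 / fs, 1.0 / fs)
    best_lag, best_c = np.nan, -np.inf
    for lag in lags:
        q = grid + lag
        if q[0] < ws_t[0] or q[-1] > ws_t[-1]:
            continue
        spd = _zscore(np.interp(q, ws_t, ws_speed))
        c = float(np.dot(ang, spd))
        if c > best_c:
            best_c, best_lag = c, float(lag)
    return best_lag


def estimate_sync_offset(kin_times, ankle_angle, ws_times, ws_speeds,
                         level_strides, window_fraction: float = 0.10,
                         max_lag: float = MAX_LAG,
                         min_strides: int = 5,
                         fs: float = RESAMPLE_FS) -> SyncEstimate:
    """Trial start offset between kinematics and wave speed, from level strides.

    Parameters
    ----------
    kin_times, ankle_angle : arrays
        Ankle dorsiflexion stream on the kinematic clock.
    ws_times, ws_speeds : arrays
        Wave-speed stream on the tensiometry clock.
    level_strides : sequence of (start_s, end_s)
        Heel-strike-delimited level strides (kinematic clock).  At least
        ``min_strides`` are required — the correlation template assumes the
        level-ground early-stance relationship between angle and load.

    Returns the per-stride lags and their mean: a POSITIVE offset means the
    wave-speed stream starts late and should be shifted earlier by that
    amount (equivalently, have ``mean_offset`` subtracted from its clock).
    """
    level_strides = list(level_strides)
    if len(level_strides) < min_strides:
        raise ValueError(
            f"need at least {min_strides} level strides for sync estimation, "
            f"got {len(level_strides)}; collect level walking or relax the "
            "level-slope threshold")
    lags = np.array([
        _stride_lag(kin_times, ankle_angle, ws_times, ws_speeds,
                    t0, t1, window_fraction, max_lag, fs)
        for t0, t1 in level_strides
    ])
    lags = lags[np.isfinite(lags)]
    if lags.size == 0:
        raise ValueError("no usable level strides (windows outside stream overlap)")
    return SyncEstimate(per_stride_lags=lags, mean_offset=float(lags.mean()),
                        n_strides_used=int(lags.size))


def apply_offset(times, values, offset: float,
                 overlap: tuple[float, float] | None = None):
    """Shift a time series earlier by ``offset`` seconds.

    The time axis has ``offset`` subtracted (undoing a late start);
    samples falling outside ``overlap`` (if given, in corrected time) are
    dropped.  ``apply_offset(apply_offset(x, d), -d)`` restores ``x`` on
    the overlap.
    """
    t = np.asarray(times, dtype=float) - offset
    v = np.asarray(values)
    if overlap is not None:
        m = (t >= overlap[0]) & (t <= overlap[1])
        t, v = t[m], v[m]
    return t, v
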