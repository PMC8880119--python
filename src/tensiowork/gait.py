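"""Gait segmentation, spatiotemporal stride metrics and terrain-slope lookup.

Strides are delimited by heel strikes detected as peaks in 10-50 Hz
band-passed accelerometer data.  Per-stride time, length (horizontal
pelvis displacement between heel strikes) and speed are computed, with
exclusion rules for implausible reconstructions.  Each stride is assigned
the terrain incline read from a course map at the stride's midpoint
displacement, then binned into even-degree slope bins from -10 to +10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps


@dataclass
class CourseMap:
    """Topographical map of course incline versus along-course position."""

    positions: np.ndarray   # m, strictly increasing
    inclines: np.ndarray    # degrees

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.inclines = np.asarray(self.inclines, dtype=float)
        if self.positions.shape != self.inclines.shape:
            raise ValueError("positions and inclines must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    def incline_at(self, position):
        """Linearly interpolated incline (degrees) at the given position(s)."""
        return np.interp(position, self.positions, self.inclines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_m": self.positions,
                             "incline_deg": self.inclines})


@dataclass
class StrideRecord:
    """One stride's timing, spatiotemporal metrics and slope assignment."""

    start: float                 # s
    end: float                   # s
    stride_time: float           # s
    stride_length: float         # m
    speed: float                 # m/s
    slope: float = np.nan        # degrees
    slope_bin: int | None = None  # even-degree bin center
    included: bool = True
    exclusion_reason: str | None = None
    participant_id: str = ""

    def exclude(self, reason: str) -> None:
        self.included = False
        self.exclusion_reason = reason


def detect_heel_strikes(accel, fs: float, band=(10.0, 50.0),
                        min_stride: float = 0.4,
                        prominence_mads: float = 2.0,
                        envelope_window: float = 0.05) -> np.ndarray:
    """Approximate heel-strike times from an accelerometer stream.

    The stream is band-pass filtered (default 10-50 Hz — the band where
    foot-impact transients dominate) and its amplitude envelope (Hilbert
    magnitude, smoothed over ``envelope_window`` seconds) is peak-picked:
    heel strikes are envelope peaks with prominence above
    ``prominence_mads`` times the envelope MAD, separated by at least
    ``min_stride`` seconds (default 0.4 s, well below any plausible
    walking stride time).  Returns times in seconds; empty with a warning
    if nothing crosses the threshold.
    """
    x = np.asarray(accel, dtype=float)
    if x.size < int(fs * min_stride):
        raise ValueError("recording shorter than one stride")
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} must lie strictly inside (0, Nyquist)")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    env = np.abs(sps.hilbert(y))
    nwin = max(int(round(envelope_window * fs)), 1)
    env = np.convolve(env, np.ones(nwin) / nwin, mode="same")
    # adaptive prominence: a MAD-scaled noise floor, but never below a
    # fraction of the strongest envelope excursion (the MAD of a sparse
    # impact train is near zero, which would admit filter-ripple peaks)
    mad = np.median(np.abs(env - np.median(env))) + 1e-300
    prominence = max(prominence_mads * mad, 0.25 * np.ptp(env))
    # impacts are rare, large transients: they must also dwarf the typical
    # envelope level, which rejects stationary noise (whose peaks would
    # otherwise pass any purely relative prominence rule)
    height = 4.0 * np.median(env)
    peaks, _ = sps.find_peaks(env, prominence=prominence, height=height,
                              distance=max(int(min_stride * fs), 1))
    if peaks.size == 0:
        warnings.warn("no heel strikes detected", stacklevel=2)
        return np.empty(0)
    # refine each peak to the impact onset: the last half-height upward
    # crossing before the peak (the envelope maximum trails the impact by
    # the burst rise time plus half the smoothing window)
    onsets = np.empty(peaks.size)
    for j, p in enumerate(peaks):
        half = 0.5 * env[p]
        i = p
        lo = max(p - int(0.2 * fs), 0)
        while i > lo and env[i] > half:
            i -= 1
        onsets[j] = i
    return onsets / fs


def stride_metrics(times, pelvis_x, heel_strikes, max_length: float = 3.0,
                   participant_id: str = "") -> list[StrideRecord]:
    """Per-stride spatiotemporal metrics from pelvis displacement.

    Stride time is the interval between successive heel strikes; stride
    length is the total horizontal pelvis displacement over that interval;
    speed is their quotient.  Strides longer than ``max_length`` meters
    (default 3 m, an implausible reconstruction) are marked excluded with
    reason ``"stride_length_gt_3m"``.
    """
    hs = np.asarray(heel_strikes, dtype=float)
    if hs.size < 2:
        raise ValueError("need at least two heel strikes")
    if np.any(np.diff(hs) <= 0):
        raise ValueError("heel-strike times must be strictly increasing")
    t = np.asarray(times, dtype=float)
    x = np.asarray(pelvis_x, dtype=float)
    records = []
    for t0, t1 in zip(hs[:-1], hs[1:]):
        dt = t1 - t0
        length = float(np.interp(t1, t, x) - np.interp(t0, t, x))
        rec = StrideRecord(start=float(t0), end=float(t1), stride_time=float(dt),
                           stride_length=length, speed=length / dt,
                           participant_id=participant_id)
        if length > max_length:
            rec.exclude("stride_length_gt_3m")
        records.append(rec)
    return records


def _moving_median(values: np.ndarray, positions: np.ndarray,
                   window: float) -> np.ndarray:
    out = np.empty_like(values)
    half = window / 2.0
    for i, p in enumerate(positions):
        m = (positions >= p - half) & (positions <= p + half)
        out[i] = np.median(values[m])
    return out


def build_course_map(pass_out, pass_back, known_length: float,
                     median_window: float = 2.0, grid_step: float = 0.5) -> CourseMap:
    """Fuse outward and return mapping passes into one course map.

    Each pass is a ``(displacement_m, incline_deg)`` pair of arrays in its
    own walking frame.  Displacements are rescaled so each pass spans
    ``known_length``; the return pass is mirrored onto outward coordinates
    with its incline sign flipped (walking back down an incline reads the
    negative of the outward reading).  The two passes are averaged on a
    common grid and a moving median over a ``median_window``-meter window
    (default 2 m) suppresses single-point glitches.
    """
    if known_length <= 0:
        raise ValueError("known_length must be positive")
    (d_out, inc_out), (d_back, inc_back) = pass_out, pass_back
    d_out = np.asarray(d_out, dtype=float)
    d_back = np.asarray(d_back, dtype=float)
    inc_out = np.asarray(inc_out, dtype=float)
    inc_back = np.asarray(inc_back, dtype=float)
    span_out = d_out[-1] - d_out[0]
    span_back = d_back[-1] - d_back[0]
    if min(span_out, span_back) <= 0:
        raise ValueError("each pass must have positive displacement span")
    if abs(span_out - span_back) / max(span_out, span_back) > 0.10:
        raise ValueError("passes cover grossly unequal lengths "
                         f"({span_out:.1f} m vs {span_back:.1f} m)")
    # rescale each pass to the surveyed course length
    p_out = (d_out - d_out[0]) * known_length / span_out
    p_back = (d_back - d_back[0]) * known_length / span_back
    # mirror the return pass onto outward coordinates, flipping incline sign
    p_back_m = known_length - p_back
    grid = np.arange(0.0, known_length + grid_step / 2, grid_step)
    i_out = np.interp(grid, p_out, inc_out)
    order = np.argsort(p_back_m)
    i_back = np.interp(grid, p_back_m[order], -inc_back[order])
    fused = 0.5 * (i_out + i_back)
    fused = _moving_median(fused, grid, median_window)
    return CourseMap(positions=grid, inclines=fused)


def bin_slope(slope_deg, bin_width: float = 2.0, max_bin: float = 10.0):
    """Nearest even-degree bin center, ties resolved toward zero.

    Odd-symmetric by construction: ``bin(-s) = -bin(s)``.
    """
    s = np.asarray(slope_deg, dtype=float)
    half = bin_width / 2.0
    mag = bin_width * np.ceil((np.abs(s) - half) / bin_width)
    mag = np.clip(mag, 0.0, max_bin)
    out = (np.sign(s) * mag).astype(int)
    if np.isscalar(slope_deg):
        return int(out)
    return out


def assign_and_bin_slope(stride: StrideRecord, midpoint_displacement: float,
                         course: CourseMap, bin_width: float = 2.0) -> StrideRecord:
    """Attach terrain slope and slope bin to a stride, in place.

    The slope is the course-map incline interpolated at the stride's
    midpoint displacement along the course.  Strides whose midpoint falls
    outside the mapped course are excluded with reason ``"off_course"``.
    """
    p0, p1 = course.positions[0], course.positions[-1]
    if not (p0 <= midpoint_displacement <= p1):
        stride.exclude("off_course")
        return stride
    stride.slope = float(course.incline_at(midpoint_displacement))
    stride.slope_bin = int(bin_slope(stride.slope, bin_width=bin_width))
    return stride


STRIDE_TABLE_COLUMNS = ("participant_id", "start_s", "end_s", "stride_time_s",
                        "stride_length_m", "speed_mps", "slope_deg",
                        "slope_bin_deg", "included", "exclusion_reason")


def strides_to_frame(strides: list[StrideRecord]) -> pd.DataFrame:
    """Stride records as a tidy table (one row per stride)."""
    if not strides:
        return pd.DataFrame(columns=list(STRIDE_TABLE_COLUMNS))
    return pd.DataFrame([{
        "participant_id": s.participant_id,
        "start_s": s.start, "end_s": s.end,
        "stride_time_s": s.stride_time, "stride_length_m": s.stride_length,
        "speed_mps": s.speed, "slope_deg": s.slope,
        "slope_bin_deg": s.slope_bin if s.slope_bin is not None else np.nan,
        "included": s.included,
        "exclusion_reason": s.exclusion_reason or "",
    } for s in strides])
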