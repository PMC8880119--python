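"""Shear-wave tensiometry signal processing.

Converts raw two-channel tendon-tap accelerometer recordings into a
quality-flagged tendon shear-wave-speed time series.  A piezo tapper
excites the tendon with a short impulsive burst every 10 ms; the burst is
picked up by two skin-mounted accelerometers spaced 8 mm apart along the
tendon.  The shear-wave travel time between the two channels is estimated
per tap by normalized cross-correlation with cosine-fit subsample peak
interpolation, and wave speed is the sensor spacing divided by that travel
time.  Squared wave speed scales with tendon tension (tensioned-beam
model), which is what makes the speed series useful downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

log = logging.getLogger(__name__)

#: default accelerometer sample rate achieved by the data logger, Hz
DEFAULT_FS = 50660.0
#: axial spacing between the two accelerometers, m
DEFAULT_SPACING = 0.008
#: tap repetition interval, s (2 ms pulse every 10 ms)
DEFAULT_TAP_INTERVAL = 0.010


@dataclass
class AccelRecording:
    """Synchronized two-channel accelerometer stream.

    Attributes
    ----------
    ch1, ch2 : ndarray
        Acceleration samples of the proximal (ch1) and distal (ch2)
        accelerometer.  Equal lengths.
    fs : float
        Sample rate, Hz.
    start_time : float
        Time of the first sample, s.
    """

    ch1: np.ndarray
    ch2: np.ndarray
    fs: float = DEFAULT_FS
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.shape != self.ch2.shape or self.ch1.ndim != 1:
            raise ValueError("channels must be equal-length 1-D arrays")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.ch1.size) / self.fs

    @property
    def duration(self) -> float:
        return self.ch1.size / self.fs


@dataclass
class WaveSpeedSeries:
    """Per-tap tendon shear-wave-speed samples.

    ``quality`` is the peak normalized cross-correlation coefficient of the
    tap's two channel windows; ``valid`` flags taps whose delay, quality and
    speed passed the plausibility rules.  Invalid samples are linearly
    interpolated in ``speeds`` for downstream continuity, but the flag is
    retained.
    """

    times: np.ndarray
    speeds: np.ndarray
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.quality is None:
            self.quality = np.ones_like(self.speeds)
        if self.valid is None:
            self.valid = np.ones(self.speeds.shape, dtype=bool)
        self.quality = np.asarray(self.quality, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.times.size == self.speeds.size == self.quality.size == self.valid.size):
            raise ValueError("fields must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def shifted(self, offset: float) -> "WaveSpeedSeries":
        """Return a copy with ``offset`` added to the time axis."""
        return replace(self, times=self.times + offset)


def bandpass_filter(rec: AccelRecording, low: float = 150.0, high: float = 1500.0,
                    order: int = 4) -> AccelRecording:
    """Zero-phase Butterworth band-pass of both channels.

    Forward-backward (``filtfilt``) application preserves tap timing, which
    matters because every downstream delay is referenced to the detected
    tap instant.
    """
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"cutoffs must satisfy 0 < {low} < {high} < Nyquist ({nyq})")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return replace(rec, ch1=sps.sosfiltfilt(sos, rec.ch1), ch2=sps.sosfiltfilt(sos, rec.ch2))


def _auto_template(x: np.ndarray, fs: float,
                   length_s: float = 0.002) -> tuple[np.ndarray, int]:
    """Highest-energy segment of ``x`` of the given length (a representative
    tap) and the index it was taken from."""
    n = max(int(round(length_s * fs)), 4)
    energy = np.convolve(x * x, np.ones(n), mode="valid")
    i = int(np.argmax(energy))
    return x[i:i + n], i


def detect_taps(rec: AccelRecording, template: np.ndarray | str = "auto",
                min_spacing: float = 0.005, threshold_mads: float = 10.0) -> np.ndarray:
    """Locate tap events on channel 1 by matched-filter cross-correlation.

    A representative tap waveform (``"auto"`` extracts the highest-energy
    2 ms segment of ch1) is cross-correlated with ch1; tap times are the
    correlation peaks above an adaptive threshold (``threshold_mads`` times
    the MAD of the correlation stream), separated by at least
    ``min_spacing`` seconds.  Returns absolute tap times in seconds; empty
    (with a warning) if nothing crosses the threshold.
    """
    self_index = None
    if isinstance(template, str):
        if template != "auto":
            raise ValueError("template must be an array or 'auto'")
        tpl, self_index = _auto_template(rec.ch1, rec.fs)
    else:
        tpl = np.asarray(template, dtype=float)
    # matched filter; lag k aligns template start with sample k
    corr = sps.correlate(rec.ch1, tpl, mode="valid")
    mad = np.median(np.abs(corr - np.median(corr))) + 1e-300
    height = threshold_mads * mad
    distance = max(int(round(min_spacing * rec.fs)), 1)
    peaks, _ = sps.find_peaks(corr, height=height, distance=distance)
    if self_index is not None and peaks.size:
        # an auto-extracted template always matches its own source segment,
        # even in tap-free noise; the trial counts as tap-bearing only if
        # the template also matches elsewhere
        near_self = np.abs(peaks - self_index) < tpl.size
        if near_self.all():
            peaks = np.empty(0, dtype=int)
    if peaks.size == 0:
        warnings.warn("no tap events found", stacklevel=2)
        log.warning("detect_taps: no tap events above %.1f MADs", threshold_mads)
        return np.empty(0)
    return rec.start_time + peaks / rec.fs


def _cosine_peak(ym1: float, y0: float, y1: float) -> float:
    """Subsample offset of a correlation peak by fitting a cosine.

    Fits y(t) = A cos(w t + phi) through the integer-lag peak and its two
    neighbours and returns the fractional offset (in samples, in (-1, 1))
    of the cosine's maximum from the central lag.  Falls back to 0 when the
    three points do not bracket a cosine peak (flat or degenerate data).
    """
    denom = 2.0 * y0
    if denom == 0:
        return 0.0
    arg = (ym1 + y1) / denom
    if not (-1.0 < arg < 1.0):
        return 0.0
    w = np.arccos(arg)
    if w == 0:
        return 0.0
    theta = np.arctan2(ym1 - y1, denom * np.sin(w))
    return float(-theta / w)


def tap_delay(ch1_window: np.ndarray, ch2_window: np.ndarray, fs: float = DEFAULT_FS,
              max_delay: float | None = None) -> tuple[float, float]:
    """Inter-channel wave travel time for one tap, with subsample resolution.

    Normalized cross-correlation of the two 4 ms post-tap windows gives an
    integer-lag delay estimate; cosine interpolation through the peak and
    its two neighbours refines it below the sample period.  Returns
    ``(delay_s, quality)`` where quality is the peak normalized correlation
    coefficient.  Flat (zero-variance) windows return ``(nan, 0.0)``.
    """
    x = np.asarray(ch1_window, dtype=float)
    y = np.asarray(ch2_window, dtype=float)
    if x.size != y.size:
        raise ValueError("windows must have equal length")
    x = x - x.mean()
    y = y - y.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return float("nan"), 0.0
    c = sps.correlate(y, x, mode="full") / (nx * ny)
    lags = np.arange(-(x.size - 1), x.size)
    if max_delay is not None:
        sel = np.abs(lags) <= max_delay * fs
        c = c[sel]
        lags = lags[sel]
    k = int(np.argmax(c))
    frac = 0.0
    if 0 < k < c.size - 1:
        frac = _cosine_peak(c[k - 1], c[k], c[k + 1])
    delay = (lags[k] + frac) / fs
    return float(delay), float(c[k])


def wave_speed_series(rec: AccelRecording, spacing: float = DEFAULT_SPACING,
                      quality_floor: float = 0.5,
                      speed_bounds: tuple[float, float] = (2.0, 150.0),
                      window: float = 0.004,
                      template: np.ndarray | str = "auto",
                      min_spacing: float = 0.005,
                      trial_id: str = "trial") -> WaveSpeedSeries:
    """Full per-tap pipeline: detect taps, estimate delays, convert to speed.

    For each detected tap, the first ``window`` seconds of both channels
    (anchored at the ch1 tap time) are cross-correlated; speed is
    ``spacing / delay``.  Taps with non-positive delay, quality below
    ``quality_floor`` or speed outside ``speed_bounds`` are flagged invalid
    and linearly interpolated.  Raises if every tap is invalid (mirrors a
    trial with inadequate tensiometer-tendon contact).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    tap_times = detect_taps(rec, template=template, min_spacing=min_spacing)
    nwin = int(round(window * rec.fs))
    times, speeds, quality, valid = [], [], [], []
    for t in tap_times:
        i0 = int(round((t - rec.start_time) * rec.fs))
        if i0 + nwin > rec.ch1.size:
            continue
        d, q = tap_delay(rec.ch1[i0:i0 + nwin], rec.ch2[i0:i0 + nwin], fs=rec.fs)
        ok = np.isfinite(d) and d > 0 and q >= quality_floor
        s = spacing / d if ok else np.nan
        if ok and not (speed_bounds[0] <= s <= speed_bounds[1]):
            ok = False
        times.append(t)
        speeds.append(s if ok else np.nan)
        quality.append(q)
        valid.append(ok)
    times = np.asarray(times)
    speeds = np.asarray(speeds)
    valid = np.asarray(valid, dtype=bool)
    if times.size == 0 or not valid.any():
        raise ValueError(f"all taps invalid in trial {trial_id!r}: "
                         "inadequate contact between the tensiometer and tendon?")
    if (~valid).any():
        speeds[~valid] = np.interp(times[~valid], times[valid], speeds[valid])
    return WaveSpeedSeries(times=times, speeds=speeds,
                           quality=np.asarray(quality), valid=valid)
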