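"""Slope-condition statistics: normalization, binning and work regressions.

Per-stride outputs are compared across terrain slopes: wave-speed curves
are normalized to each participant's mean peak in the level condition and
averaged in 2-degree slope bins on a common % gait-cycle grid; per-stride
net work is zero-referenced to each participant's level-condition mean
and regressed on slope separately for declines and inclines (ordinary
least squares, two-sided coefficient tests at alpha = 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: strides with |slope| at or below this are "level" (the 0-degree bin)
LEVEL_SLOPE_MAX = 1.0
ALPHA = 0.05
GAIT_GRID_POINTS = 101


@dataclass
class SlopeWorkRegression:
    """One segment's (incline or decline) fitted work-slope sensitivity."""

    muscle: str
    segment: str            # "incline" | "decline"
    coefficient: float      # J/kg per degree
    intercept: float        # J/kg
    p_value: float
    n_strides: int
    stderr: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_strides < 2:
            raise ValueError("regression needs at least 2 strides")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        d = asdict(self)
        d["significant"] = self.significant
        return d


def resample_to_gait_cycle(times, values, n_points: int = GAIT_GRID_POINTS):
    """Linearly resample one stride's signal onto a 0-100% gait-cycle grid."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples per stride")
    grid = np.linspace(t[0], t[-1], n_points)
    return np.interp(grid, t, v)


def normalize_wave_speed_curves(curves: pd.DataFrame,
                                level_max: float = LEVEL_SLOPE_MAX) -> pd.DataFrame:
    """Normalize per-stride wave-speed curves to participant level peaks.

    ``curves`` must carry columns ``participant_id``, ``slope_deg`` and a
    ``curve`` column of per-stride arrays (any common length).  Each curve
    is divided by its participant's mean per-stride maximum over level
    strides (|slope| <= ``level_max``).  Scale-invariant: multiplying a
    participant's raw speeds by any constant leaves the output unchanged.
    """
    out = curves.copy()
    normalized = []
    for pid, grp in curves.groupby("participant_id", sort=False):
        level = grp[np.abs(grp["slope_deg"]) <= level_max]
        if len(level) == 0:
            raise ValueError(f"participant {pid!r} has no level strides; "
                             "cannot normalize wave-speed curves")
        ref = float(np.mean([np.max(c) for c in level["curve"]]))
        for i in grp.index:
            normalized.append((i, np.asarray(curves.at[i, "curve"]) / ref))
    normalized.sort(key=lambda p: p[0])
    out["curve"] = [c for _, c in normalized]
    return out


def bin_average_curves(curves: pd.DataFrame,
                       bins=tuple(range(-10, 12, 2)),
                       n_points: int = GAIT_GRID_POINTS) -> pd.DataFrame:
    """Across-participant mean curve per slope bin on a % gait-cycle grid.

    ``curves`` must carry ``slope_bin_deg`` and ``curve`` columns (curves
    already normalized; resampled here to ``n_points`` if needed).  Empty
    bins are omitted with a warning.  Returns a long-format table
    (pct_gait_cycle, bin_center_deg, mean_normalized_speed, n_strides).
    """
    pct = np.linspace(0.0, 100.0, n_points)
    rows = []
    for b in bins:
        grp = curves[curves["slope_bin_deg"] == b]
        if len(grp) == 0:
            warnings.warn(f"slope bin {b:+d} deg is empty", stacklevel=2)
            continue
        stack = np.vstack([
            np.interp(pct, np.linspace(0, 100, len(c)), np.asarray(c))
            for c in grp["curve"]])
        mean = stack.mean(axis=0)
        rows.append(pd.DataFrame({"pct_gait_cycle": pct,
                                  "bin_center_deg": b,
                                  "mean_normalized_speed": mean,
                                  "n_strides": len(grp)}))
    if not rows:
        return pd.DataFrame(columns=["pct_gait_cycle", "bin_center_deg",
                                     "mean_normalized_speed", "n_strides"])
    return pd.concat(rows, ignore_index=True)


def zero_reference_work(work, participant_ids, level_mask) -> np.ndarray:
    """Change in net work from each participant's level-condition mean.

    Subtracts the participant-specific mean work over level strides,
    removing inter-participant offsets so strides can be pooled.  Raises
    if any participant lacks level strides.
    """
    w = np.asarray(work, dtype=float)
    pid = np.asarray(participant_ids)
    level = np.asarray(level_mask, dtype=bool)
    out = np.empty_like(w)
    for p in pd.unique(pid):
        m = pid == p
        if not level[m].any():
            raise ValueError(f"participant {p!r} has no level strides; "
                             "cannot zero-reference work")
        out[m] = w[m] - w[m & level].mean()
    return out


def _fit_segment(dw: np.ndarray, slopes: np.ndarray, muscle: str,
                 segment: str, min_strides: int) -> SlopeWorkRegression:
    if dw.size < min_strides:
        raise ValueError(f"{segment} segment has {dw.size} strides; "
                         f"need at least {min_strides}")
    res = sm.OLS(dw, sm.add_constant(slopes)).fit()
    ci = res.conf_int(alpha=ALPHA)
    return SlopeWorkRegression(
        muscle=muscle, segment=segment,
        coefficient=float(res.params[1]), intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]), n_strides=int(dw.size),
        stderr=float(res.bse[1]),
        ci_low=float(ci[1][0]), ci_high=float(ci[1][1]))


def fit_slope_sensitivity(delta_work, slopes, muscle: str,
                          min_strides: int = 10,
                          include_level_in_both: bool = True
                          ) -> tuple[SlopeWorkRegression, SlopeWorkRegression]:
    """OLS sensitivity of zero-referenced net work to slope, per segment.

    Declines are slopes <= 0 and inclines slopes >= 0 (level strides enter
    both segments by default, config-exposed).  Returns
    ``(decline, incline)`` regressions with two-sided p-values and 95%
    confidence intervals on the slope coefficient.
    """
    dw = np.asarray(delta_work, dtype=float)
    s = np.asarray(slopes, dtype=float)
    if dw.size != s.size:
        raise ValueError("delta_work and slopes must be paired")
    if include_level_in_both:
        dec, inc = s <= 0.0, s >= 0.0
    else:
        dec, inc = s < 0.0, s > 0.0
    decline = _fit_segment(dw[dec], s[dec], muscle, "decline", min_strides)
    incline = _fit_segment(dw[inc], s[inc], muscle, "incline", min_strides)
    return decline, incline
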