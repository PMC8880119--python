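"""Normalization, bin averaging, zero-referencing and slope regressions."""

import numpy as np
import pandas as pd
import pytest

from tensiowork.mechanics import mtu_power, stride_work
from tensiowork.slope_stats import (bin_average_curves, fit_slope_sensitivity,
                                    normalize_wave_speed_curves,
                                    zero_reference_work)
from tensiowork.synthetic import make_cohort_workset


def _curve_table(rows):
    return pd.DataFrame([{"participant_id": p, "slope_deg": s,
                          "slope_bin_deg": b, "curve": np.asarray(c)}
                         for p, s, b, c in rows])


class TestNormalization:
    def test_level_mean_peak_is_one(self):
        tbl = _curve_table([
            ("A", 0.0, 0, [1.0, 4.0, 2.0]),
            ("A", 0.5, 0, [1.0, 6.0, 2.0]),
            ("A", 8.0, 8, [2.0, 10.0, 3.0]),
        ])
        out = normalize_wave_speed_curves(tbl)
        level_peaks = [np.max(c) for c in out["curve"][:2]]
        assert np.mean(level_peaks) == pytest.approx(1.0)

    def test_scale_invariance(self):
        base = _curve_table([("A", 0.0, 0, [1.0, 4.0, 2.0]),
                             ("A", 6.0, 6, [2.0, 8.0, 3.0])])
        doubled = base.copy()
        doubled["curve"] = [2 * c for c in base["curve"]]
        a = normalize_wave_speed_curves(base)
        b = normalize_wave_speed_curves(doubled)
        for ca, cb in zip(a["curve"], b["curve"]):
            np.testing.assert_allclose(ca, cb)

    def test_missing_level_strides_rejected(self):
        tbl = _curve_table([("A", 6.0, 6, [1.0, 2.0])])
        with pytest.raises(ValueError, match="level"):
            normalize_wave_speed_curves(tbl)


class TestBinAveraging:
    def test_identical_curves_idempotent(self):
        c = np.linspace(0.8, 1.2, 101)
        tbl = _curve_table([("A", 4.0, 4, c), ("B", 4.2, 4, c)])
        out = bin_average_curves(tbl, bins=(4,))
        np.testing.assert_allclose(out["mean_normalized_speed"], c)
        assert (out["n_strides"] == 2).all()

    def test_constant_curves_average(self):
        tbl = _curve_table([("A", 0.0, 0, np.full(50, 0.8)),
                            ("B", 0.0, 0, np.full(50, 1.2))])
        out = bin_average_curves(tbl, bins=(0,))
        np.testing.assert_allclose(out["mean_normalized_speed"], 1.0)

    def test_empty_bin_warns_and_is_omitted(self):
        tbl = _curve_table([("A", 0.0, 0, np.ones(11))])
        with pytest.warns(UserWarning, match="empty"):
            out = bin_average_curves(tbl, bins=(0, 8))
        assert set(out["bin_center_deg"]) == {0}


class TestZeroReferencing:
    def test_level_mean_is_zero_per_participant(self):
        w = np.array([1.0, 1.2, 2.0, 3.0, 3.4, 4.0])
        pid = np.array(["A", "A", "A", "B", "B", "B"])
        level = np.array([True, True, False, True, True, False])
        dw = zero_reference_work(w, pid, level)
        assert dw[level][:2].mean() == pytest.approx(0.0)
        assert dw[level][2:].mean() == pytest.approx(0.0)

    def test_participant_constant_shift_invariance(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, 40)
        pid = np.repeat(["A", "B"], 20)
        level = np.tile([True] * 5 + [False] * 15, 2)
        shifted = w + np.where(pid == "A", 3.7, -1.2)
        np.testing.assert_allclose(zero_reference_work(w, pid, level),
                                   zero_reference_work(shifted, pid, level),
                                   atol=1e-12)

    def test_offsets_collapse_to_common_line(self):
        # two participants, same slope law, different offsets
        slopes = np.tile(np.linspace(-10, 10, 21), 2)
        pid = np.repeat(["A", "B"], 21)
        w = 0.02 * slopes + np.where(pid == "A", 1.0, 5.0)
        level = np.abs(slopes) <= 1.0
        dw = zero_reference_work(w, pid, level)
        np.testing.assert_allclose(dw, 0.02 * slopes, atol=1e-12)

    def test_missing_level_strides_rejected(self):
        with pytest.raises(ValueError, match="level"):
            zero_reference_work([1.0, 2.0], ["A", "A"], [False, False])


class TestSlopeSensitivity:
    def test_exact_line_recovered(self):
        slopes = np.linspace(-10, 0, 30)
        dec, _ = fit_slope_sensitivity(
            np.r_[0.02 * slopes, 0.05 * np.linspace(0.1, 10, 30)],
            np.r_[slopes, np.linspace(0.1, 10, 30)], "soleus")
        assert dec.coefficient == pytest.approx(0.02, abs=1e-12)
        assert dec.p_value < 0.05

    def test_piecewise_exact_recovery_both_segments(self):
        slopes = np.linspace(-10, 10, 201)
        dw = np.where(slopes < 0, 0.02 * slopes, 0.01 * slopes)
        dec, inc = fit_slope_sensitivity(dw, slopes, "soleus")
        assert dec.coefficient == pytest.approx(0.02, abs=1e-9)
        assert inc.coefficient == pytest.approx(0.01, abs=1e-9)

    def test_noise_only_not_significant(self):
        rng = np.random.default_rng(5)
        slopes = rng.uniform(-10, 10, 400)
        dw = rng.normal(0, 0.05, 400)
        dec, inc = fit_slope_sensitivity(dw, slopes, "soleus")
        for seg in (dec, inc):
            assert abs(seg.coefficient) < 2 * seg.stderr
            assert not seg.significant

    def test_coefficient_equivariance(self):
        rng = np.random.default_rng(2)
        slopes = rng.uniform(-10, 10, 100)
        dw = 0.015 * slopes + rng.normal(0, 0.02, 100)
        d1, i1 = fit_slope_sensitivity(dw, slopes, "m")
        d3, i3 = fit_slope_sensitivity(3.0 * dw, slopes, "m")
        assert d3.coefficient == pytest.approx(3 * d1.coefficient)
        assert i3.coefficient == pytest.approx(3 * i1.coefficient)

    def test_short_segment_rejected(self):
        slopes = np.r_[np.linspace(-10, -1, 3), np.linspace(1, 10, 30)]
        with pytest.raises(ValueError, match="decline"):
            fit_slope_sensitivity(0.01 * slopes, slopes, "m")

    def test_cohort_recovery_within_ci(self):
        """Generator truth must fall in the pipeline's fitted 95% CIs."""
        cw = make_cohort_workset(n_participants=6, strides_per=100, seed=13)
        rows = []
        for st_ in cw.strides:
            ws, _, _ = stride_work(mtu_power(st_.FS, st_.VS), st_.times)
            wg, _, _ = stride_work(mtu_power(st_.FG, st_.VG), st_.times)
            rows.append((st_.participant_id, st_.slope, ws, wg))
        df = pd.DataFrame(rows, columns=["pid", "slope", "WS", "WG"])
        level = np.abs(df["slope"].to_numpy()) <= 1.0
        truth = {("soleus", "decline"): 0.02, ("soleus", "incline"): 0.01,
                 ("gastrocnemius", "decline"): 0.008,
                 ("gastrocnemius", "incline"): -0.008}
        for muscle, col in (("soleus", "WS"), ("gastrocnemius", "WG")):
            dw = zero_reference_work(df[col].to_numpy(),
                                     df["pid"].to_numpy(), level)
            for seg in fit_slope_sensitivity(dw, df["slope"].to_numpy(),
                                             muscle):
                assert seg.ci_low <= truth[(muscle, seg.segment)] <= seg.ci_high
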