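"""Generator contracts: determinism, truth retention, physical consistency."""

import numpy as np
import pytest

from tensiowork.calibration import wave_speed_from_moment
from tensiowork.mechanics import mtu_power, stride_work
from tensiowork.synthetic import (GaitPattern, ParticipantProfile, TrialSpec,
                                  default_gait_pattern, make_cohort_workset,
                                  make_sway_trial, make_trial,
                                  piecewise_work_truth, render_tap_recording,
                                  tap_wavelet)
from tensiowork.tensiometry import WaveSpeedSeries, tap_delay


def _constant_pattern(moment=27.0, n=101):
    """Pattern whose tendon load (hence wave speed) is constant."""
    pct = np.linspace(0, 100, n)
    speed = float(wave_speed_from_moment(moment))
    return GaitPattern(pct=pct,
                       ankle_template=np.zeros(n), knee_template=np.zeros(n),
                       speed_template=np.full(n, speed),
                       moment_template=np.full(n, moment))


class TestTrialGenerator:
    def test_constant_moment_maps_to_constant_speed(self, profile):
        # inverting M = 0.05 S^2 - 17 at 27 N*m gives sqrt(44 / 0.05)
        pat = _constant_pattern(moment=27.0)
        spec = TrialSpec(n_strides=3, slope_sequence=np.zeros(3),
                         noise_scale=0.0, seed=0)
        trial = make_trial(profile, pat, spec)
        expected = np.sqrt((27.0 + 17.0) / 0.05)
        assert expected == pytest.approx(29.66, abs=0.01)
        np.testing.assert_allclose(trial.truth["wave_speeds"], expected)

    def test_stride_count_matches_spec(self, pattern, profile):
        spec = TrialSpec(n_strides=10, slope_sequence=np.zeros(10), seed=1)
        trial = make_trial(profile, pattern, spec)
        hs = trial.truth["heel_strikes"]
        assert hs.size == 11  # 10 stride intervals
        np.testing.assert_allclose(np.diff(hs),
                                   trial.truth["stride_times"], rtol=1e-9)

    def test_moment_below_calibration_floor_rejected(self, pattern):
        bad = ParticipantProfile(id="bad", calib_intercept=50.0)
        spec = TrialSpec(n_strides=2, slope_sequence=np.zeros(2), seed=0)
        with pytest.raises(ValueError, match="floor"):
            make_trial(bad, pattern, spec)

    def test_determinism(self, pattern, profile):
        spec = TrialSpec(n_strides=4, slope_sequence=np.zeros(4),
                         noise_scale=0.01, seed=9)
        a = make_trial(profile, pattern, spec)
        b = make_trial(profile, pattern, spec)
        np.testing.assert_array_equal(a.kinematics.ankle_deg,
                                      b.kinematics.ankle_deg)
        np.testing.assert_array_equal(a.wave_speed_stream.speeds,
                                      b.wave_speed_stream.speeds)

    def test_slope_sequence_validated(self):
        with pytest.raises(ValueError):
            TrialSpec(n_strides=2, slope_sequence=np.array([0.0, 15.0]))
        with pytest.raises(ValueError):
            TrialSpec(n_strides=2, slope_sequence=np.zeros(2), sync_delay=0.2)


class TestTapRendering:
    def test_constant_speed_exact_delay(self):
        truth = WaveSpeedSeries(times=np.arange(0.01, 0.3, 0.01),
                                speeds=np.full(29, 40.0))
        rec = render_tap_recording(truth, noise_scale=0.0, seed=0)
        # inter-channel delay must equal spacing / speed = 200 us per tap
        fs = rec.fs
        nwin = int(0.004 * fs)
        for tk in truth.times[2:10]:
            i0 = int(round((tk - rec.start_time) * fs))
            d, q = tap_delay(rec.ch1[i0:i0 + nwin], rec.ch2[i0:i0 + nwin],
                             fs=fs)
            assert d == pytest.approx(0.008 / 40.0, rel=1e-3)
            assert q > 0.9

    def test_seeded_rendering_is_reproducible(self):
        truth = WaveSpeedSeries(times=np.arange(0.01, 0.1, 0.01),
                                speeds=np.full(9, 35.0))
        a = render_tap_recording(truth, noise_scale=1e-5, seed=5)
        b = render_tap_recording(truth, noise_scale=1e-5, seed=5)
        np.testing.assert_array_equal(a.ch1, b.ch1)
        np.testing.assert_array_equal(a.ch2, b.ch2)

    def test_noise_level_matches_request(self):
        truth = WaveSpeedSeries(times=np.arange(0.01, 0.5, 0.01),
                                speeds=np.full(49, 35.0))
        clean = render_tap_recording(truth, noise_scale=0.0)
        noise_scale = 3e-5  # 0.003% of signal amplitude
        noisy = render_tap_recording(truth, noise_scale=noise_scale, seed=2)
        resid = noisy.ch1 - clean.ch1
        ratio = resid.std() / np.abs(clean.ch1).max()
        assert ratio == pytest.approx(noise_scale, rel=0.05)
        resid2 = noisy.ch2 - clean.ch2
        assert resid2.std() > resid.std()  # distal channel is noisier

    def test_negative_noise_rejected(self):
        truth = WaveSpeedSeries(times=[0.01, 0.02], speeds=[30.0, 30.0])
        with pytest.raises(ValueError):
            render_tap_recording(truth, noise_scale=-1e-6)

    def test_wavelet_duration(self):
        t = np.linspace(-0.001, 0.004, 1000)
        w = tap_wavelet(t)
        assert np.all(w[t < 0] == 0) and np.all(w[t > 0.002] == 0)


class TestSwayTrial:
    def test_impact_spike_index(self, profile):
        sway = make_sway_trial(profile, duration=1.0, impact_time=0.35,
                               seed=0)
        assert np.argmax(sway.Fz) == 350

    def test_noiseless_moment_consistency(self, profile):
        sway = make_sway_trial(profile, duration=5.0, noise_scale=0.0, seed=0)
        # truth moment and wave-speed truth are calibration-consistent
        M = sway.truth["moment"]
        S = sway.wave_speed.speeds
        np.testing.assert_allclose(profile.calib_slope * S**2
                                   + profile.calib_intercept, M, atol=1e-9)

    def test_impact_outside_trial_rejected(self, profile):
        with pytest.raises(ValueError):
            make_sway_trial(profile, duration=1.0, impact_time=2.0)


class TestCohortWorkset:
    def test_degenerate_cohort_all_equal(self):
        cw = make_cohort_workset(n_participants=2, strides_per=20,
                                 soleus_sens_decline=0.0,
                                 soleus_sens_incline=0.0,
                                 gastroc_sens_decline=0.0,
                                 gastroc_sens_incline=0.0,
                                 work_noise_sd=0.0, level_work_sd=(0.0, 0.0),
                                 seed=1)
        assert cw.truth["WS_true"].nunique() == 1
        assert cw.truth["WG_true"].nunique() == 1

    def test_piecewise_law_and_integrator_agreement(self):
        assert piecewise_work_truth(10.0, 0.2, 0.02, 0.01) == pytest.approx(0.3)
        cw = make_cohort_workset(n_participants=1, strides_per=20,
                                 work_noise_sd=0.0, level_work_sd=(0.0, 0.0),
                                 seed=3)
        for st_, (_, row) in zip(cw.strides, cw.truth.iterrows()):
            ws, _, _ = stride_work(mtu_power(st_.FS, st_.VS), st_.times)
            assert ws == pytest.approx(row["WS_true"], abs=1e-3)

    def test_determinism(self):
        a = make_cohort_workset(n_participants=2, strides_per=20, seed=4)
        b = make_cohort_workset(n_participants=2, strides_per=20, seed=4)
        assert a.truth.equals(b.truth)
        np.testing.assert_array_equal(a.strides[5].VS, b.strides[5].VS)

    def test_too_few_strides_rejected(self):
        with pytest.raises(ValueError):
            make_cohort_workset(strides_per=5)


class TestCalibrationRoundTrip:
    def test_profile_round_trip_identity(self, profile):
        # applying then inverting the participant calibration is identity
        M = np.linspace(-10, 150, 500)
        S = np.sqrt((M - profile.calib_intercept) / profile.calib_slope)
        back = profile.calib_slope * S**2 + profile.calib_intercept
        np.testing.assert_allclose(back, M, rtol=1e-9, atol=1e-9)
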