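"""Localization feature bank: steps, strides, heading, MFCC, GPS."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from harloc import features_localization as fz
from harloc import synthio
from harloc.errors import ValidationError
from harloc.io_formats import AudioRecording, GpsTrack
from harloc.preprocess import TriaxialSignal


def triax(z, x=None, y=None):
    z = np.asarray(z, dtype=float)
    return TriaxialSignal(x if x is not None else np.zeros_like(z),
                          y if y is not None else np.zeros_like(z), z)


# --- MFCC brute-force oracle ------------------------------------------------

def mfcc_frame_oracle(frame, fb, n_fft, n_coeffs, floor):
    """Direct DFT + explicit triangle weights + naive DCT summation."""
    n = len(frame)
    padded = np.zeros(n_fft)
    padded[:n] = frame
    n_bins = n_fft // 2 + 1
    power = np.empty(n_bins)
    for k in range(n_bins):
        re = sum(padded[m] * np.cos(-2 * np.pi * k * m / n_fft) for m in range(n_fft))
        im = sum(padded[m] * np.sin(-2 * np.pi * k * m / n_fft) for m in range(n_fft))
        power[k] = re * re + im * im
    n_filters = fb.shape[0]
    log_e = np.empty(n_filters)
    for i in range(n_filters):
        log_e[i] = np.log(max(sum(fb[i, k] * power[k] for k in range(n_bins)), floor))
    out = np.empty(n_coeffs)
    for k in range(n_coeffs):
        out[k] = sum(log_e[n - 1] * np.cos(np.pi * k * (n - 0.5) / n_filters)
                     for n in range(1, n_filters + 1))
    return out


class TestSteps:
    def test_recovers_generator_ground_truth_noiseless(self):
        spec = synthio.ScenarioSpec(duration_s=10.0,
                                    activities=[("walking", 0.0, 10.0)],
                                    noise_sd=0.0)
        rec, truth = synthio.generate_recording(spec)
        sig = TriaxialSignal(rec.channels["ax"], rec.channels["ay"], rec.channels["az"])
        det = fz.detect_steps(sig, rec.sample_rate_hz)
        assert det.count == truth.total_steps == 10

    def test_constant_signal_has_no_steps(self):
        assert fz.detect_steps(triax(np.full(100, 9.81)), 10.0).count == 0

    def test_monotone_ramp_has_no_steps(self):
        assert fz.detect_steps(triax(np.linspace(0, 10, 100)), 10.0).count == 0

    @given(st.floats(0.1, 20.0), st.floats(0.0, 50.0))
    def test_invariant_under_scale_and_offset(self, scale, offset):
        t = np.arange(100) / 10.0
        base = 9.81 + 2.0 * np.sin(2 * np.pi * 1.0 * t + 0.3)
        c0 = fz.detect_steps(triax(base), 10.0).count
        c1 = fz.detect_steps(triax(scale * base + offset), 10.0).count
        assert c0 == c1

    def test_refractory_period_merges_close_peaks(self):
        a = np.full(60, 10.0)
        a[[20, 22]] = [15.0, 16.0]  # two peaks 0.2 s apart at 10 Hz
        a[40] = 14.0
        assert fz.detect_steps(triax(a), 10.0).count == 3
        assert fz.detect_steps(triax(a), 10.0, min_gap_s=0.25).count == 2


class TestStrides:
    def test_stride_length_is_delta_t_times_speed(self):
        t = np.arange(0, 10, 0.1)
        a = np.sin(2 * np.pi * t / 1.25)
        est = fz.estimate_strides(a, 10.0, speed_const_mps=1.2)
        np.testing.assert_allclose(est.stride_lengths_m, est.delta_t_s * 1.2)

    def test_sinusoid_valleys_recur_at_period(self):
        t = np.arange(0, 20, 0.1)
        a = np.sin(2 * np.pi * t / 1.25)
        est = fz.estimate_strides(a, 10.0)
        assert len(est.delta_t_s) >= 5
        assert 1.15 <= np.median(est.delta_t_s) <= 1.35

    def test_zero_acceleration_yields_no_strides(self, caplog):
        with caplog.at_level("WARNING"):
            est = fz.estimate_strides(np.zeros(100), 10.0)
        assert len(est.stride_lengths_m) == 0

    def test_lengths_scale_linearly_with_speed_const(self):
        t = np.arange(0, 12, 0.1)
        a = np.sin(2 * np.pi * t)
        e1 = fz.estimate_strides(a, 10.0, speed_const_mps=1.0)
        e2 = fz.estimate_strides(a, 10.0, speed_const_mps=2.5)
        np.testing.assert_allclose(e2.stride_lengths_m, 2.5 * e1.stride_lengths_m)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            fz.estimate_strides(np.zeros(20), 10.0)


class TestHeading:
    @pytest.mark.parametrize("mx,my,expected", [
        (1.0, 0.0, 0.0), (0.0, 1.0, 90.0), (-1.0, 0.0, 180.0), (0.0, -1.0, 270.0),
    ])
    def test_cardinal_directions(self, mx, my, expected):
        series = fz.heading_angles(triax(np.zeros(1), x=np.array([mx]), y=np.array([my])))
        assert series.theta_deg[0] == pytest.approx(expected, abs=1e-9)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_antipodal_flip_adds_180(self, mx, my):
        if abs(mx) < 1e-6 and abs(my) < 1e-6:
            return
        t1 = fz.heading_angles(triax(np.zeros(1), x=np.array([mx]), y=np.array([my]))).theta_deg[0]
        t2 = fz.heading_angles(triax(np.zeros(1), x=np.array([-mx]), y=np.array([-my]))).theta_deg[0]
        assert (t1 + 180.0) % 360.0 == pytest.approx(t2 % 360.0, abs=1e-6)

    def test_undefined_sample_flagged(self):
        series = fz.heading_angles(triax(np.zeros(2), x=np.array([0.0, 1.0]),
                                         y=np.array([0.0, 0.0])))
        assert series.undefined[0] and not series.undefined[1]
        assert series.theta_deg[0] == 0.0


class TestMfcc:
    def test_constant_log_energies_concentrate_in_c0(self):
        log_e = np.full(26, np.log(3.0))
        coeffs = fz._dct_log_energies(log_e, 13)
        assert coeffs[0] == pytest.approx(26 * np.log(3.0), rel=1e-12)
        np.testing.assert_allclose(coeffs[1:], 0.0, atol=1e-9)

    def test_tone_lands_in_nearest_filter(self):
        spec = synthio.ScenarioSpec(duration_s=0.5, activities=[("standing", 0.0, 0.5)],
                                    noise_sd=0.0)
        audio = synthio.generate_audio(spec, tone_hz=1000.0, audio_rate_hz=8000.0)
        mspec = fz.MfccSpec()
        fb = fz.mel_filterbank(mspec.n_filters, 256, 8000.0)
        frame = audio.samples[:200] * np.hanning(200)
        energies = fz.mel_energies(frame, fb, 256)
        centers = fz.filter_center_freqs_hz(mspec, 8000.0)
        assert abs(centers[int(np.argmax(energies))] - 1000.0) == \
            pytest.approx(np.min(np.abs(centers - 1000.0)), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rate = 800.0
        audio = AudioRecording(rng.normal(scale=0.2, size=int(0.1 * rate)), rate)
        mspec = fz.MfccSpec(n_filters=10, n_coeffs=6)
        coeffs = fz.mfcc(audio, mspec)
        frame_len = int(round(mspec.frame_s * rate))
        n_fft = 32
        fb = fz.mel_filterbank(10, n_fft, rate)
        window = np.hanning(frame_len + 1)[:-1]  # periodic Hann
        frame = audio.samples[:frame_len] * window
        expected = mfcc_frame_oracle(frame, fb, n_fft, 6, mspec.energy_floor)
        np.testing.assert_allclose(coeffs[0], expected, atol=1e-6)

    def test_silent_audio_floors(self, caplog):
        audio = AudioRecording(np.zeros(4000), 8000.0)
        with caplog.at_level("WARNING"):
            coeffs = fz.mfcc(audio)
        c0_floor = 26 * np.log(fz.MfccSpec().energy_floor)
        np.testing.assert_allclose(coeffs[:, 0], c0_floor, rtol=1e-12)
        np.testing.assert_allclose(coeffs[:, 1:], 0.0, atol=1e-8)


class TestGps:
    def test_stationary_track_zero_speeds(self):
        track = GpsTrack(times_s=np.arange(5.0), lat_deg=np.full(5, 47.0),
                         lon_deg=np.full(5, 8.0))
        kin = fz.gps_kinematics(track)
        assert kin.max_speed_mps == 0.0

    def test_synthetic_track_speed_recovered(self):
        spec = synthio.ScenarioSpec(duration_s=60.0,
                                    activities=[("walking", 0.0, 60.0)],
                                    heading_deg=123.0, noise_sd=0.0)
        track = synthio.generate_gps_track(spec, speed_mps=1.0)
        kin = fz.gps_kinematics(track)
        assert 0.99 <= kin.mean_speed_mps <= 1.01

    def test_millidegree_latitude_distance(self):
        d = float(fz.haversine_m(47.0, 8.0, 47.001, 8.0))
        assert abs(d - 111.2) / 111.2 < 0.01

    def test_single_fix_flagged(self):
        track = GpsTrack(times_s=np.array([0.0]), lat_deg=np.array([47.0]),
                         lon_deg=np.array([8.0]))
        kin = fz.gps_kinematics(track)
        assert not kin.defined and kin.mean_speed_mps == 0.0


class TestRowAssembly:
    def make_bundle(self, rng, with_audio=True, with_gps=True):
        t = np.arange(50) / 10.0
        imu = triax(9.81 + 2 * np.sin(2 * np.pi * t) + rng.normal(0, 0.05, 50))
        mag = TriaxialSignal(np.full(50, 0.7), np.full(50, 0.7), np.zeros(50))
        audio = AudioRecording(0.3 * np.sin(2 * np.pi * 440 * np.arange(8000) / 8000.0),
                               8000.0) if with_audio else None
        gps = GpsTrack(times_s=np.arange(5.0), lat_deg=47.0 + 1e-5 * np.arange(5),
                       lon_deg=np.full(5, 8.0)) if with_gps else None
        return fz.SegmentBundle(imu=imu, imu_rate_hz=10.0, mag=mag, audio=audio, gps=gps)

    def test_full_bundle_has_39_columns(self, rng):
        row = fz.localization_feature_row(self.make_bundle(rng))
        assert len(row) == 39  # 2 step + 2 stride + 2 heading + 26 mfcc + 3 gps + 4 flags

    def test_identical_bundles_identical_rows(self, rng):
        b = self.make_bundle(rng)
        assert fz.localization_feature_row(b) == fz.localization_feature_row(b)

    def test_missing_audio_fills_zero_with_flag(self, rng):
        row = fz.localization_feature_row(self.make_bundle(rng, with_audio=False))
        assert row["audio_present"] == 0.0
        assert all(row[f"mfcc{k}_mean"] == 0.0 for k in range(13))

    def test_all_modalities_missing_rejected(self):
        bundle = fz.SegmentBundle(imu=None, imu_rate_hz=10.0)
        with pytest.raises(ValidationError):
            fz.localization_feature_row(bundle)
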