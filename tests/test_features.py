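"""Feature extraction: WAV I/O, mel filterbank, MFCCs, centroid, spectrogram."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import signal as sps

from vocsig import CohortSpec, generate_cohort
from vocsig.features import (
    AudioFormatError,
    MfccConfig,
    SpectrogramParams,
    extract_feature_table,
    load_wav,
    mel_filterbank,
    mel_scale,
    mel_to_hz,
    meow_config,
    mfcc_per_call,
    n_frames,
    purr_config,
    read_feature_csv,
    spectral_centroid,
    spectrogram,
    to_mono,
    write_feature_csv,
    write_wav,
    duration,
)
from vocsig.synth import CallRecording


def _tone(freq, sr, dur, amp=0.5):
    t = np.arange(int(sr * dur)) / sr
    return CallRecording(amp * np.sin(2 * np.pi * freq * t), sr, "a", "s", "meow")


@pytest.fixture(scope="module")
def meow_call():
    spec = CohortSpec(2, 2, "meow", sample_rate=16_000.0, seed=9)
    return generate_cohort(spec)[0]


# ------------------------------------------------------------------- WAV I/O

class TestWavIO:
    def test_roundtrip_within_16bit_quantization(self, meow_call, tmp_path):
        path = tmp_path / "call.wav"
        write_wav(path, meow_call)
        back = load_wav(path)
        assert back.sample_rate == 16_000
        assert np.max(np.abs(back.samples - meow_call.samples)) <= 1.0 / 32768

    def test_empty_file_raises_format_error(self, tmp_path):
        path = tmp_path / "empty.wav"
        path.write_bytes(b"")
        with pytest.raises(AudioFormatError):
            load_wav(path)

    def test_garbage_file_raises_format_error(self, tmp_path):
        path = tmp_path / "junk.wav"
        path.write_bytes(b"not audio at all" * 10)
        with pytest.raises(AudioFormatError):
            load_wav(path)


class TestToMono:
    def test_identical_channels_collapse_to_one(self):
        left = np.linspace(-0.5, 0.5, 100)
        rec = CallRecording(np.column_stack([left, left]), 1000.0)
        np.testing.assert_allclose(to_mono(rec).samples, left)

    def test_antiphase_channels_cancel(self):
        left = np.sin(np.linspace(0, 10, 100))
        rec = CallRecording(np.column_stack([left, -left]), 1000.0)
        np.testing.assert_allclose(to_mono(rec).samples, 0.0, atol=1e-15)

    def test_constant_channels_average(self):
        rec = CallRecording(np.column_stack([np.full(10, 0.5), np.full(10, 0.1)]), 1000.0)
        np.testing.assert_allclose(to_mono(rec).samples, 0.3)

    def test_three_channels_rejected(self):
        rec = CallRecording(np.zeros((10, 3)), 1000.0)
        with pytest.raises(AudioFormatError):
            to_mono(rec)


# ----------------------------------------------------------------- mel scale

class TestMelScale:
    def test_zero_maps_to_zero(self):
        assert mel_scale(0.0) == 0.0

    def test_one_khz_maps_near_1000_mel(self):
        m = mel_scale(1000.0)
        assert abs(m - 1000.0) / 1000.0 < 1e-3

    def test_compressive_above_1khz(self):
        # quadrupling the frequency less than quadruples the mel value
        assert mel_scale(4000.0) < 4 * mel_scale(1000.0)
        assert mel_scale(4000.0) == pytest.approx(2146.06, abs=0.01)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            mel_scale(-1.0)

    def test_strictly_monotone_and_invertible(self):
        f = np.linspace(0, 48_000, 1001)
        m = mel_scale(f)
        assert np.all(np.diff(m) > 0)
        back = mel_to_hz(m[1:])
        assert np.max(np.abs(back - f[1:]) / f[1:]) < 1e-6


class TestMelFilterbank:
    def test_filters_are_unimodal_triangles(self):
        fb = mel_filterbank(meow_config(), 1024, 16_000.0)
        for row in fb:
            d = np.sign(np.diff(row[row > 0]))
            # weights rise then fall: at most one sign change
            changes = np.sum(np.abs(np.diff(d[d != 0])) > 0)
            assert changes <= 1

    def test_centers_monotone_increasing(self):
        fb = mel_filterbank(meow_config(), 1024, 16_000.0)
        centers = np.argmax(fb, axis=1)
        assert np.all(np.diff(centers) > 0)

    def test_centers_equally_spaced_on_mel_axis(self):
        cfg = meow_config()
        fb = mel_filterbank(cfg, 4096, 16_000.0)
        bin_freqs = np.arange(fb.shape[1]) * 16_000.0 / 4096
        centers_mel = mel_scale(bin_freqs[np.argmax(fb, axis=1)])
        spacing = np.diff(centers_mel)
        expected = mel_scale(8000.0) / (cfg.n_filters + 1)
        assert np.all(np.abs(spacing - expected) < mel_scale(2 * 16_000.0 / 4096))

    def test_full_coverage_between_outer_centers(self):
        fb = mel_filterbank(meow_config(), 1024, 16_000.0)
        centers = np.argmax(fb, axis=1)
        total = fb.sum(axis=0)
        assert np.all(total[centers[0] : centers[-1] + 1] > 0)

    def test_unresolvable_filter_count_rejected(self):
        with pytest.raises(ValueError, match="n_filters|FFT"):
            mel_filterbank(meow_config(n_filters=40), 64, 16_000.0)


# --------------------------------------------------------------------- MFCCs

def _mfcc_oracle(x, sr, cfg):
    """Brute-force MFCC: explicit loops, np.fft, hand-built DCT matrix."""
    win = int(round(cfg.window_length * sr))
    hop = int(round(win * cfg.hop_fraction))
    nfft = 1
    while nfft < win:
        nfft *= 2
    fmax = sr / 2 if cfg.fmax is None else cfg.fmax
    mel_pts = [
        mel_scale(cfg.fmin) + i * (mel_scale(fmax) - mel_scale(cfg.fmin)) / (cfg.n_filters + 1)
        for i in range(cfg.n_filters + 2)
    ]
    hz_pts = [700.0 * (10 ** (m / 2595.0) - 1.0) for m in mel_pts]
    bin_freqs = [k * sr / nfft for k in range(nfft // 2 + 1)]
    fb = np.zeros((cfg.n_filters, len(bin_freqs)))
    for m in range(cfg.n_filters):
        lo, mid, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        for k, f in enumerate(bin_freqs):
            if lo < f <= mid:
                fb[m, k] = (f - lo) / (mid - lo)
            elif mid < f < hi:
                fb[m, k] = (hi - f) / (hi - mid)
            elif f == lo or f == hi:
                fb[m, k] = 0.0
    ham = np.hamming(win)
    energies = []
    start = 0
    while start + win <= len(x):
        spec = np.abs(np.fft.rfft(x[start : start + win] * ham, nfft))
        energies.append(fb @ spec)
        start += hop
    energies = np.array(energies)
    floor = cfg.log_floor * energies.max()
    logE = np.log(energies + floor)
    n = cfg.n_filters
    dct = np.zeros((n, n))
    for k in range(n):
        for j in range(n):
            scale = math.sqrt(1.0 / n) if k == 0 else math.sqrt(2.0 / n)
            dct[k, j] = scale * math.cos(math.pi * k * (2 * j + 1) / (2 * n))
    ceps = logE @ dct.T
    return ceps[:, 1 : cfg.n_coefficients + 1].mean(axis=0)


class TestMfcc:
    def test_frame_count_for_072s_call_at_96khz(self):
        assert n_frames(69_120, 96_000.0, meow_config()) == 47

    def test_amplitude_invariance(self, meow_call):
        cfg = meow_config()
        ref = mfcc_per_call(meow_call, cfg)
        for gain in (0.1, 0.5, 2.0, 10.0):
            scaled = CallRecording(meow_call.samples * gain, meow_call.sample_rate)
            got = mfcc_per_call(scaled, cfg)
            assert np.max(np.abs(got - ref)) < 1e-8

    def test_matches_independent_brute_force_oracle(self):
        sr = 8000.0
        t = np.arange(int(0.3 * sr)) / sr
        chirp = sps.chirp(t, f0=300, f1=2500, t1=0.3) * np.hanning(t.size)
        rec = CallRecording(chirp, sr)
        cfg = meow_config()
        got = mfcc_per_call(rec, cfg)
        expected = _mfcc_oracle(chirp, sr, cfg)
        assert np.max(np.abs(got - expected)) < 1e-6

    def test_too_short_recording_mentions_window(self):
        rec = CallRecording(np.zeros(100), 16_000.0)
        with pytest.raises(ValueError, match="window"):
            mfcc_per_call(rec, purr_config())

    def test_silence_yields_finite_coefficients(self):
        rec = CallRecording(np.zeros(1600), 16_000.0)
        coeffs = mfcc_per_call(rec, meow_config())
        assert np.all(np.isfinite(coeffs))

    def test_both_window_configs_give_ten_finite_coefficients(self):
        meow = generate_cohort(CohortSpec(2, 2, "meow", sample_rate=16_000.0, seed=3))
        purr = generate_cohort(CohortSpec(2, 2, "purr", sample_rate=4000.0, seed=3))
        for rec, cfg in [(r, meow_config()) for r in meow] + [
            (r, purr_config()) for r in purr
        ]:
            coeffs = mfcc_per_call(rec, cfg)
            assert coeffs.shape == (10,) and np.all(np.isfinite(coeffs))


# -------------------------------------------------- duration, centroid, STFT

class TestDurationAndCentroid:
    def test_duration_from_sample_count(self):
        rec = CallRecording(np.zeros(69_120), 96_000.0)
        assert duration(rec) == pytest.approx(0.72)
        assert duration(CallRecording(np.zeros(1), 96_000.0)) == pytest.approx(1 / 96_000)

    def test_pure_tone_centroid(self):
        rec = _tone(1000.0, 16_000.0, 1.0)
        assert abs(spectral_centroid(rec) - 1000.0) <= 16_000.0 / rec.samples.size + 1.0

    def test_two_tone_mixture_centroid_near_600(self):
        sr = 8000.0
        t = np.arange(int(sr)) / sr
        wave = 0.4 * np.sin(2 * np.pi * 200 * t) + 0.4 * np.sin(2 * np.pi * 1000 * t)
        rec = CallRecording(wave, sr)
        assert abs(spectral_centroid(rec) - 600.0) < 10.0

    def test_white_noise_centroid_near_half_nyquist(self, rng):
        sr = 96_000.0
        rec = CallRecording(0.5 * rng.standard_normal(int(0.5 * sr)), sr)
        assert abs(spectral_centroid(rec) - 24_000.0) / 24_000.0 < 0.05

    def test_all_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            spectral_centroid(CallRecording(np.zeros(100), 1000.0))


class TestSpectrogram:
    def test_resolution_report_at_96khz(self):
        rec = _tone(1000.0, 96_000.0, 0.1)
        _, _, _, info = spectrogram(rec, SpectrogramParams())
        assert info["bin_width_hz"] == pytest.approx(93.75)
        assert info["hop_samples"] == 128
        assert info["hop_time_s"] * 1000 == pytest.approx(1.333, abs=0.01)

    def test_zero_signal_gives_zero_matrix(self):
        rec = CallRecording(np.zeros(4096), 96_000.0)
        _, _, sxx, _ = spectrogram(rec)
        assert np.all(sxx == 0)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            SpectrogramParams(overlap=1.0).validate()


# ------------------------------------------------------------ feature tables

class TestFeatureTableIO:
    def test_csv_roundtrip(self, tmp_path, meow_call):
        table = extract_feature_table([meow_call])
        path = tmp_path / "features.csv"
        write_feature_csv(table, path)
        back = read_feature_csv(path)
        np.testing.assert_allclose(
            back.filter(like="mfcc").to_numpy(), table.filter(like="mfcc").to_numpy()
        )

    def test_fuzzy_headers_and_delimiter_sniffing(self, tmp_path):
        path = tmp_path / "data_s1_like.csv"
        header = "Cat ID;Call Type;Duration;Spectral Centroid;" + ";".join(
            f"MFCC {i}" for i in range(1, 11)
        )
        row = "cat01;meow;0.72;1738;" + ";".join(str(0.1 * i) for i in range(1, 11))
        path.write_text(header + "\n" + row + "\n" + row + "\n")
        df = read_feature_csv(path)
        assert df.loc[0, "individual_id"] == "cat01"
        assert df.loc[0, "duration_s"] == pytest.approx(0.72)
        assert df.loc[0, "mfcc10"] == pytest.approx(1.0)

    def test_missing_feature_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("individual_id,duration_s\na,1.0\n")
        with pytest.raises(ValueError, match="missing"):
            read_feature_csv(path)
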