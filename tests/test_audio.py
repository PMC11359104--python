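"""Audio front end: WAV loading, filtering, windowing, STFT, image mapping."""

import numpy as np
import pytest
from scipy import signal
from scipy.io import wavfile

import hivesense as hs
from hivesense.audio import (
    HOP,
    LOWPASS_HZ,
    LOWPASS_ORDER,
    N_FFT,
    RATE,
    mel_excerpt_bounds,
    mel_filterbank,
    normalize_unit,
)


def _write_wav(path, duration, rate=RATE, freq=220.0, dtype=np.uint8):
    t = np.arange(int(duration * rate)) / rate
    x = 0.5 * np.sin(2 * np.pi * freq * t)
    if dtype == np.uint8:
        data = np.clip(np.round(x * 128 + 128), 0, 255).astype(np.uint8)
    else:
        data = (x * 32767).astype(np.int16)
    wavfile.write(str(path), rate, data)
    return path


class TestLoadWav:
    def test_sample_count_and_range(self, tmp_path):
        rec = hs.load_wav(_write_wav(tmp_path / "a.wav", 60.0))
        assert len(rec.samples) == 1_323_000
        assert rec.rate == RATE
        assert np.all(np.abs(rec.samples) <= 1.0)

    def test_thirty_seconds_accepted_and_yields_two_windows(self, tmp_path):
        rec = hs.load_wav(_write_wav(tmp_path / "b.wav", 30.0))
        assert len(hs.split_windows(rec)) == 2

    def test_too_short_rejected(self, tmp_path):
        with pytest.raises(hs.TooShortError):
            hs.load_wav(_write_wav(tmp_path / "c.wav", 15.0))

    def test_missing_file(self, tmp_path):
        with pytest.raises(hs.InputError):
            hs.load_wav(tmp_path / "nope.wav")

    def test_other_rate_resampled_with_warning(self, tmp_path, caplog):
        path = _write_wav(tmp_path / "d.wav", 30.0, rate=44_100, dtype=np.int16)
        with caplog.at_level("WARNING"):
            rec = hs.load_wav(path)
        assert rec.rate == RATE
        assert abs(rec.duration - 30.0) < 0.01
        assert any("resampling" in r.message for r in caplog.records)


class TestLowpass:
    def test_stopband_tone_attenuated_40db(self):
        t = np.arange(30 * RATE) / RATE
        rec = hs.AudioRecording(samples=0.5 * np.sin(2 * np.pi * 5000.0 * t))
        out = hs.lowpass(rec)
        ratio = np.sqrt(np.mean(out.samples**2)) / np.sqrt(np.mean(rec.samples**2))
        # analytic check of the chosen design: zero-phase Butterworth response at 5 kHz
        sos = signal.butter(LOWPASS_ORDER, LOWPASS_HZ, btype="low", fs=RATE, output="sos")
        _, h = signal.sosfreqz(sos, worN=[5000.0], fs=RATE)
        assert np.abs(h[0]) ** 2 < 10 ** (-40 / 20)  # filtfilt squares the magnitude
        assert 20 * np.log10(ratio) < -40

    def test_passband_tone_preserved_within_1db(self):
        t = np.arange(30 * RATE) / RATE
        rec = hs.AudioRecording(samples=0.5 * np.sin(2 * np.pi * 200.0 * t))
        out = hs.lowpass(rec)
        ratio = np.sqrt(np.mean(out.samples**2)) / np.sqrt(np.mean(rec.samples**2))
        assert abs(20 * np.log10(ratio)) < 1.0

    def test_zero_signal_stays_zero(self):
        rec = hs.AudioRecording(samples=np.zeros(30 * RATE))
        assert np.allclose(hs.lowpass(rec).samples, 0.0)

    def test_cutoff_beyond_nyquist_rejected(self):
        rec = hs.AudioRecording(samples=np.zeros(30 * RATE))
        with pytest.raises(hs.ParameterError):
            hs.lowpass(rec, cutoff=12_000.0)


class TestSplitWindows:
    @pytest.mark.parametrize("duration,expected", [(60, 5), (30, 2), (35, 2), (90, 8)])
    def test_window_counts(self, duration, expected):
        rec = hs.AudioRecording(samples=np.zeros(duration * RATE))
        assert len(hs.split_windows(rec)) == expected

    def test_first_window_kept_when_not_discarding(self):
        rec = hs.AudioRecording(samples=np.arange(30 * RATE, dtype=float) % 7)
        segs = hs.split_windows(rec, discard_first=False)
        assert len(segs) == 3
        np.testing.assert_array_equal(segs[0].samples, rec.samples[: 10 * RATE])

    def test_too_few_windows(self):
        rec = hs.AudioRecording(samples=np.zeros(15 * RATE))
        with pytest.raises(hs.TooShortError):
            hs.split_windows(rec)


class TestSfft:
    def test_shape(self, tone_recording):
        assert hs.sfft(tone_recording).magnitudes.shape == (513, 862)

    def test_tone_lands_in_row_50(self, tone_recording):
        mags = hs.sfft(tone_recording).magnitudes
        assert int(np.argmax(mags.mean(axis=1))) == 50

    def test_matches_brute_force_dft_frame(self, tone_recording):
        # naive O(N^2) DFT of the first centred frame as an independent oracle
        x = np.pad(tone_recording.samples, N_FFT // 2)[:N_FFT]
        w = signal.get_window("hann", N_FFT)
        n = np.arange(N_FFT)
        k = np.arange(513)
        dft = np.abs((w * x)[None, :] @ np.exp(-2j * np.pi * k[:, None] * n[None, :] / N_FFT).T)
        np.testing.assert_allclose(hs.sfft(tone_recording).magnitudes[:, 0], dft.ravel(),
                                   rtol=1e-8, atol=1e-8)

    def test_zero_segment_all_zero(self):
        rec = hs.AudioRecording(samples=np.zeros(10 * RATE))
        assert np.all(hs.sfft(rec).magnitudes == 0)

    def test_wrong_length_rejected(self):
        with pytest.raises(hs.ShapeError):
            hs.sfft(hs.AudioRecording(samples=np.zeros(9 * RATE)))


class TestCropAndAverage:
    def test_identical_matrices_average_to_their_crop(self, tone_recording):
        m = hs.sfft(tone_recording)
        mean = hs.crop_and_average([m] * 4)
        np.testing.assert_array_equal(mean.A, m.magnitudes[:224, :224])
        assert mean.n_windows == 4

    def test_constant_matrices_average(self):
        m0 = hs.SpectrogramMatrix(magnitudes=np.zeros((513, 862)))
        m2 = hs.SpectrogramMatrix(magnitudes=np.full((513, 862), 2.0))
        np.testing.assert_array_equal(hs.crop_and_average([m0, m2]).A, np.ones((224, 224)))

    def test_empty_list_rejected(self):
        with pytest.raises(hs.InputError):
            hs.crop_and_average([])


class TestGrayImage:
    def test_minmax_endpoints(self):
        A = np.zeros((224, 224))
        A[0, 0], A[1, 1] = 0.0, 4.0
        A[2, 2] = 1.0
        img = hs.to_gray_image(hs.MeanResponseMatrix(A=A))
        assert img.pixels[1, 1] == 255 and img.pixels[0, 0] == 0

    def test_half_up_rounding_of_midpoint(self):
        # value 2 on a 0..4 range maps to 255*0.5 = 127.5 -> 128 (half-up)
        A = np.zeros((224, 224))
        A[0, :4] = [0.0, 1.0, 2.0, 4.0]
        img = hs.to_gray_image(hs.MeanResponseMatrix(A=A))
        assert img.pixels[0, 2] == 128

    def test_constant_matrix_maps_to_black(self):
        img = hs.to_gray_image(hs.MeanResponseMatrix(A=np.full((224, 224), 3.3)))
        assert np.all(img.pixels == 0)

    def test_pixel_range_invariant(self, late_swarm_recording):
        res = hs.process_recording(late_swarm_recording)
        assert res.image.pixels.min() == 0 and res.image.pixels.max() == 255

    def test_save_roundtrip_png(self, tmp_path, late_swarm_recording):
        from PIL import Image

        res = hs.process_recording(late_swarm_recording)
        path = tmp_path / "img.png"
        res.image.save(path)
        np.testing.assert_array_equal(np.asarray(Image.open(path)), res.image.pixels)


class TestMelDisplay:
    def test_excerpt_rule(self):
        assert mel_excerpt_bounds(60.0) == (12.0, 32.0)
        assert mel_excerpt_bounds(90.0) == (18.0, 38.0)

    def test_filterbank_covers_all_bins(self):
        fb = mel_filterbank(n_mels=128)
        assert fb.shape == (128, 513)
        assert np.all(fb.sum(axis=0)[1:-1] > 0)

    def test_silence_renders_at_log_floor(self, tmp_path):
        rec = hs.AudioRecording(samples=np.zeros(30 * RATE))
        out = hs.mel_display_image(rec, tmp_path / "mel.png")
        assert (tmp_path / "mel.png").exists() and out.endswith(".png")

    def test_too_short_rejected(self):
        rec = hs.AudioRecording(samples=np.zeros(25 * RATE))
        with pytest.raises(hs.TooShortError):
            hs.mel_display_image(rec, "unused.png")


def test_normalize_unit_is_idempotent_on_unit_data():
    rng = np.random.default_rng(0)
    A = rng.random((224, 224))
    u = normalize_unit(A)
    np.testing.assert_allclose(normalize_unit(u), u, atol=1e-12)
    assert u.min() == 0.0 and u.max() == 1.0
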