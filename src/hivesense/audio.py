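"""Sound-to-image front end of the hive monitor.

A field recording (nominally 8-bit unsigned PCM at 22,050 Hz, 30-90 s) is
low-pass filtered to the 0-2.5 kHz band where colony sound lives, split into
10 s windows (the first window is discarded: microphone start-up noise),
short-time Fourier transformed into 513 x 862 magnitude matrices, cropped to
their first 224 rows/columns, and averaged into a single 224 x 224 mean
response matrix ``A``.  ``A`` is min-max normalised and quantised to a
single-channel grayscale image for the image classifier; a Mel-scale
log-amplitude spectrogram of a 20 s excerpt is rendered for display.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .errors import InputError, ParameterError, ShapeError, TooShortError

log = logging.getLogger(__name__)

#: Internal sampling rate; all recordings are converted to this rate.
RATE = 22_050
#: STFT transform length -> 513 frequency rows (RATE/1024 ~ 21.53 Hz per row).
N_FFT = 1024
#: STFT hop; with centred (half-window padded) frames a 10 s segment yields 862 frames.
HOP = 256
SPEC_SHAPE = (513, 862)
#: Side length of the cropped mean-response matrix and model-input image.
CROP = 224
WINDOW_SECONDS = 10.0
LOWPASS_HZ = 2500.0
#: Default Butterworth order for the anti-noise low-pass (applied zero-phase).
LOWPASS_ORDER = 10
MIN_DURATION = 20.0  # below this not a single window survives the first-window discard


@dataclass
class AudioRecording:
    """PCM audio held as centred floats in [-1, 1]."""

    samples: np.ndarray
    rate: int = RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.ndim != 1:
            raise ShapeError("AudioRecording expects a 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("audio samples contain non-finite values")

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return len(self.samples) / self.rate


@dataclass
class SpectrogramMatrix:
    """Magnitude spectrogram of one 10 s window (513 x 862)."""

    magnitudes: np.ndarray
    freq_step: float = RATE / N_FFT
    time_origin: float = 0.0

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.magnitudes.shape != SPEC_SHAPE:
            raise ShapeError(
                f"spectrogram must be {SPEC_SHAPE}, got {self.magnitudes.shape}"
            )
        if not np.all(np.isfinite(self.magnitudes)) or np.any(self.magnitudes < 0):
            raise InputError("spectrogram magnitudes must be finite and non-negative")


@dataclass
class MeanResponseMatrix:
    """Elementwise mean of the cropped window spectrograms (symbol A, 224 x 224)."""

    A: np.ndarray
    n_windows: int = 1

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.A.shape != (CROP, CROP):
            raise ShapeError(f"mean response matrix must be {(CROP, CROP)}, got {self.A.shape}")


@dataclass
class GrayImage:
    """Single-channel 8-bit image fed to the audio classifier."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != (CROP, CROP):
            raise ShapeError(f"gray image must be {(CROP, CROP)}, got {self.pixels.shape}")

    def save(self, path: str | os.PathLike) -> None:
        """Write the image; format follows the extension (PNG lossless, JPEG lossy)."""
        from PIL import Image

        Image.fromarray(self.pixels, mode="L").save(os.fspath(path))


# ---------------------------------------------------------------------------
# WAV loading
# ---------------------------------------------------------------------------

def _to_float(samples: np.ndarray) -> np.ndarray:
    """Convert integer PCM (native 8-bit unsigned, or 16/32-bit) to centred floats."""
    if samples.dtype == np.uint8:
        return (samples.astype(np.float64) - 128.0) / 128.0
    if samples.dtype == np.int16:
        return samples.astype(np.float64) / 32768.0
    if samples.dtype == np.int32:
        return samples.astype(np.float64) / 2147483648.0
    if np.issubdtype(samples.dtype, np.floating):
        return samples.astype(np.float64)
    raise InputError(f"unsupported WAV sample format {samples.dtype}")


def load_wav(path: str | os.PathLike) -> AudioRecording:
    """Read a WAV file into an :class:`AudioRecording` at the internal 22,050 Hz rate.

    Multi-channel audio is mixed down to mono.  Recordings at other sampling
    rates are resampled (with a logged warning) so that downstream window and
    frame counts stay fixed.  Recordings shorter than 20 s cannot yield a
    single usable window once the start-up window is discarded and are
    rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        rate, samples = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on corrupt files
        raise InputError(f"could not read WAV file {path}: {exc}") from exc
    data = _to_float(np.asarray(samples))
    if data.ndim == 2:
        data = data.mean(axis=1)
    if rate != RATE:
        log.warning("resampling %s from %d Hz to %d Hz", path, rate, RATE)
        from math import gcd

        g = gcd(RATE, int(rate))
        data = signal.resample_poly(data, RATE // g, int(rate) // g)
        rate = RATE
    rec = AudioRecording(samples=data, rate=int(rate))
    if rec.duration < MIN_DURATION:
        raise TooShortError(
            f"recording is {rec.duration:.1f} s; at least {MIN_DURATION:.0f} s are "
            "needed to keep one 10 s window after the start-up discard"
        )
    return rec


def save_wav(path: str | os.PathLike, rec: AudioRecording) -> None:
    """Write a recording as 8-bit unsigned PCM (the device's native format)."""
    q = np.clip(np.round(rec.samples * 128.0 + 128.0), 0, 255).astype(np.uint8)
    wavfile.write(os.fspath(path), rec.rate, q)


# ---------------------------------------------------------------------------
# Filtering and windowing
# ---------------------------------------------------------------------------

def lowpass(rec: AudioRecording, cutoff: float = LOWPASS_HZ, order: int = LOWPASS_ORDER) -> AudioRecording:
    """Zero-phase Butterworth low-pass keeping the 0-``cutoff`` Hz colony band."""
    nyquist = rec.rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ParameterError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff}")
    sos = signal.butter(order, cutoff, btype="low", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return AudioRecording(samples=filtered, rate=rec.rate)


def split_windows(
    rec: AudioRecording,
    window: float = WINDOW_SECONDS,
    discard_first: bool = True,
) -> list[AudioRecording]:
    """Cut the recording into consecutive non-overlapping ``window``-second chunks.

    The first chunk is dropped by default (microphone start-up noise); a
    trailing partial chunk is always dropped.
    """
    if window <= 0:
        raise ParameterError("window length must be positive")
    step = int(round(window * rec.rate))
    n_full = len(rec.samples) // step
    if n_full < 2:
        raise TooShortError(
            f"recording of {rec.duration:.1f} s yields {n_full} full {window:.0f} s "
            "window(s); at least 2 are needed (the first is discarded)"
        )
    start = 1 if discard_first else 0
    return [
        AudioRecording(samples=rec.samples[i * step:(i + 1) * step], rate=rec.rate)
        for i in range(start, n_full)
    ]


# ---------------------------------------------------------------------------
# Short-time Fourier transform
# ---------------------------------------------------------------------------

def sfft(segment: AudioRecording, time_origin: float = 0.0) -> SpectrogramMatrix:
    """Magnitude STFT of a 10 s window: 1024-point transform, Hann window, hop 256.

    Frames are centred by padding half a transform length of zeros on each
    side, so a 220,500-sample segment yields exactly 862 frames and 513
    frequency rows covering 0-11,025 Hz in steps of 22,050/1024 Hz.
    """
    x = segment.samples
    expected = int(round(WINDOW_SECONDS * RATE))
    if segment.rate != RATE or len(x) != expected:
        raise ShapeError(
            f"sfft expects a {WINDOW_SECONDS:.0f} s segment at {RATE} Hz "
            f"({expected} samples); got {len(x)} samples at {segment.rate} Hz"
        )
    pad = N_FFT // 2
    xp = np.pad(x, pad)
    n_frames = 1 + (len(xp) - N_FFT) // HOP
    idx = np.arange(N_FFT)[None, :] + HOP * np.arange(n_frames)[:, None]
    frames = xp[idx] * signal.get_window("hann", N_FFT)
    mags = np.abs(np.fft.rfft(frames, n=N_FFT, axis=1)).T  # rows = frequency
    return SpectrogramMatrix(magnitudes=mags, time_origin=time_origin)


def crop_and_average(matrices: list[SpectrogramMatrix]) -> MeanResponseMatrix:
    """Crop each spectrogram to its first 224 rows/columns and average elementwise."""
    if not matrices:
        raise InputError("crop_and_average needs at least one spectrogram")
    crops = np.stack([m.magnitudes[:CROP, :CROP] for m in matrices])
    return MeanResponseMatrix(A=crops.mean(axis=0), n_windows=len(matrices))


def normalize_unit(A: MeanResponseMatrix | np.ndarray) -> np.ndarray:
    """Min-max scale a matrix to [0, 1]; a constant matrix maps to all zeros."""
    arr = A.A if isinstance(A, MeanResponseMatrix) else np.asarray(A, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def to_gray_image(A: MeanResponseMatrix) -> GrayImage:
    """Quantise the min-max normalised mean response to 8-bit grayscale.

    Rounding is half-up (floor(x + 0.5)) so pixel values are bit-exact across
    platforms; for non-constant input the extremes 0 and 255 are attained.
    """
    if not np.all(np.isfinite(A.A)):
        raise InputError("mean response matrix contains non-finite values")
    unit = normalize_unit(A)
    pixels = np.floor(unit * 255.0 + 0.5).astype(np.uint8)
    return GrayImage(pixels=pixels)


# ---------------------------------------------------------------------------
# Mel display spectrogram
# ---------------------------------------------------------------------------

def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int = 128, n_fft: int = N_FFT, rate: int = RATE) -> np.ndarray:
    """Triangular Mel filterbank (HTK mel scale) mapping 513 bins to ``n_mels`` bands."""
    n_bins = n_fft // 2 + 1
    freqs = np.arange(n_bins) * rate / n_fft
    edges = _mel_to_hz(np.linspace(0.0, _hz_to_mel(rate / 2.0), n_mels + 2))
    fb = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_excerpt_bounds(duration: float, window: float = 20.0) -> tuple[float, float]:
    """Start/end (seconds) of the display excerpt: [0.2 * duration, +20 s].

    The start is clamped so the excerpt always fits inside the recording.
    """
    start = min(0.2 * duration, max(duration - window, 0.0))
    return start, start + min(window, duration)


def mel_display_image(
    rec: AudioRecording,
    path: str | os.PathLike,
    n_mels: int = 128,
    floor_db: float = -80.0,
) -> str:
    """Render the Mel-frequency, log-amplitude display spectrogram of a 20 s excerpt.

    Purely a visualisation: 128 Mel bands, dB amplitude floored at
    ``floor_db`` relative to the peak, written as a PNG raster.
    """
    if rec.duration < 30.0:
        raise TooShortError("Mel display needs a recording of at least 30 s")
    start, end = mel_excerpt_bounds(rec.duration)
    chunk = rec.samples[int(start * rec.rate):int(end * rec.rate)]
    pad = N_FFT // 2
    xp = np.pad(chunk, pad)
    n_frames = 1 + (len(xp) - N_FFT) // HOP
    idx = np.arange(N_FFT)[None, :] + HOP * np.arange(n_frames)[:, None]
    frames = xp[idx] * signal.get_window("hann", N_FFT)
    power = np.abs(np.fft.rfft(frames, n=N_FFT, axis=1)).T ** 2
    mel_power = mel_filterbank(n_mels=n_mels, rate=rec.rate) @ power
    ref = mel_power.max()
    db = 10.0 * np.log10(np.maximum(mel_power, 1e-30) / max(ref, 1e-30))
    db = np.maximum(db, floor_db)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3), dpi=120)
    ax.imshow(db, origin="lower", aspect="auto", cmap="magma",
              extent=(start, end, 0, n_mels))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("Mel band")
    fig.tight_layout()
    fig.savefig(os.fspath(path))
    plt.close(fig)
    return os.fspath(path)


# ---------------------------------------------------------------------------
# Convenience: the full front end in one call
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything the audio front end produces for one recording."""

    mean_response: MeanResponseMatrix
    image: GrayImage
    n_windows: int
    normalized: np.ndarray = field(repr=False, default=None)


def process_recording(rec: AudioRecording, cutoff: float = LOWPASS_HZ) -> PipelineResult:
    """Run filter -> window split -> STFT -> crop/average -> grayscale image."""
    filtered = lowpass(rec, cutoff=cutoff)
    segments = split_windows(filtered)
    mats = [
        sfft(seg, time_origin=(i + 1) * WINDOW_SECONDS)
        for i, seg in enumerate(segments)
    ]
    mean = crop_and_average(mats)
    return PipelineResult(
        mean_response=mean,
        image=to_gray_image(mean),
        n_windows=len(mats),
        normalized=normalize_unit(mean),
    )
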