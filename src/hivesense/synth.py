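"""Class-conditioned synthetic fixtures: sensor days and hive audio.

No public corpus of in-hive recordings or probe measurements exists, so every
other module is exercised on generated data.

*Sensor days* are drawn uniformly inside each condition class's stated
temperature/humidity envelope, with per-hour Gaussian jitter near the DHT22
sensor accuracy (0.5 degC / 2 %RH), and re-annotated by the fuzzy engine;
draws whose annotation disagrees with the requested class are rejected and
redrawn, so generated labels agree with the fuzzy annotation by construction.

*Audio* is a sum of band-limited harmonic stacks whose band energies follow
each acoustic class's characteristic frequency regions (e.g. the late-swarm
class concentrates energy at 400-500 Hz) over a white-noise floor, quantised
to the device's 8-bit format.  Only the band-level energy structure matters
to the pipeline under test; no attempt is made to imitate real bee timbre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import RATE, AudioRecording
from .errors import InputError, ParameterError
from .fuzzy import (
    HOURS_PER_DAY,
    MAX_PROBES,
    MIN_PROBES,
    N_CLASSES,
    OUTLIER_CLASS,
    ClassLabel,
    SensorBatch,
    annotate_day,
    annotate_days,
)

# ---------------------------------------------------------------------------
# Sensor-day generation
# ---------------------------------------------------------------------------

#: Per-hour measurement jitter, close to the DHT22 accuracy figures.
TEMP_JITTER = 0.5    # degC
HUMIDITY_JITTER = 2.0  # %RH

#: Day-level sampling envelopes (uniform) per condition class:
#: probe temperature, lid offset relative to the probe mean, humidity.
SENSOR_ENVELOPES: dict[int, dict] = {
    0: {"probe": (1.0, 9.0), "lid": (-10.0, -1.0), "humidity": (25.0, 90.0)},
    1: {  # two humid-and-cool regimes
        "regimes": [
            {"probe": (12.0, 19.0), "lid_offset": (-2.0, 2.0), "humidity": (83.0, 96.0)},
            {"probe": (21.0, 27.0), "lid_offset": (-2.0, 2.0), "humidity": (92.0, 98.0)},
        ]
    },
    2: {"probe": (33.0, 36.0), "lid_offset": (-5.0, -1.0), "humidity": (40.0, 65.0)},
    3: {"probe": (40.0, 45.0), "lid_offset": (1.0, 3.5), "humidity": (35.0, 70.0)},
    # class 4: a normal-looking day corrupted by out-of-range readings
    4: {"probe": (25.0, 36.0), "lid_offset": (-5.0, 0.0), "humidity": (35.0, 70.0),
        "corrupt_humidity": (120.0, 250.0), "corrupt_temp": (-60.0, -30.0)},
}

#: Rejection-sampling cap; hitting it signals an envelope/rule inconsistency.
MAX_ATTEMPTS = 1000


def _draw_day(class_id: int, n_probes: int, rng: np.random.Generator) -> np.ndarray:
    env = SENSOR_ENVELOPES[class_id]
    if "regimes" in env:
        env = env["regimes"][rng.integers(len(env["regimes"]))]
    probe_base = rng.uniform(*env["probe"])
    if "lid" in env:  # absolute lid range (freezing-lid class)
        lid_base = rng.uniform(*env["lid"])
    else:
        lid_base = probe_base + rng.uniform(*env["lid_offset"])
    hum_base = rng.uniform(*env["humidity"])

    values = np.empty((HOURS_PER_DAY, n_probes + 2))
    values[:, :n_probes] = probe_base + rng.normal(0.0, TEMP_JITTER, size=(HOURS_PER_DAY, n_probes))
    values[:, n_probes] = lid_base + rng.normal(0.0, TEMP_JITTER, size=HOURS_PER_DAY)
    values[:, n_probes + 1] = np.clip(
        hum_base + rng.normal(0.0, HUMIDITY_JITTER, size=HOURS_PER_DAY), 1.0, 99.0
    )
    if class_id == OUTLIER_CLASS:
        spec = SENSOR_ENVELOPES[OUTLIER_CLASS]
        n_bad = int(rng.integers(1, 4))
        for _ in range(n_bad):
            hour = int(rng.integers(HOURS_PER_DAY))
            col = int(rng.integers(n_probes + 2))
            rng_range = spec["corrupt_humidity"] if col == n_probes + 1 else spec["corrupt_temp"]
            values[hour, col] = rng.uniform(*rng_range)
    return values


def gen_sensor_day(class_id: int, n_probes: int, seed: int | np.random.Generator) -> tuple[SensorBatch, ClassLabel]:
    """Generate one sensor day of the requested class, fuzzy-verified.

    Rejection sampling redraws until the fuzzy annotation matches the
    requested class (an envelope inconsistency raises after 1000 attempts).
    Deterministic for a fixed seed.
    """
    if class_id not in range(N_CLASSES):
        raise ParameterError(f"class_id must be 0-{N_CLASSES - 1}, got {class_id}")
    if not MIN_PROBES <= n_probes <= MAX_PROBES:
        raise ParameterError(f"n_probes must be {MIN_PROBES}-{MAX_PROBES}, got {n_probes}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(MAX_ATTEMPTS):
        batch = SensorBatch(values=_draw_day(class_id, n_probes, rng), n_probes=n_probes)
        label = annotate_day(batch)
        if label.id == class_id:
            return batch, label
    raise InputError(
        f"could not generate a class-{class_id} day in {MAX_ATTEMPTS} attempts; "
        "the sampling envelope disagrees with the fuzzy rules"
    )


def gen_dataset(
    per_class: int = 16_000,
    n_probes: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced labelled dataset of ``5 * per_class`` flattened sensor days.

    Returns ``(X, y)`` with X of shape (5*per_class, 24*(n_probes+2)).
    Seed-reproducible; generation is vectorised with chunked rejection.
    """
    if per_class < 1:
        raise ParameterError("per_class must be >= 1")
    if not MIN_PROBES <= n_probes <= MAX_PROBES:
        raise ParameterError(f"n_probes must be {MIN_PROBES}-{MAX_PROBES}, got {n_probes}")
    rng = np.random.default_rng(seed)
    width = HOURS_PER_DAY * (n_probes + 2)
    X = np.empty((N_CLASSES * per_class, width))
    y = np.repeat(np.arange(N_CLASSES), per_class)
    for cls in range(N_CLASSES):
        rows = []
        need = per_class
        attempts = 0
        while need > 0:
            chunk = np.stack([
                _draw_day(cls, n_probes, rng).reshape(-1)
                for _ in range(min(need + 32, 2 * per_class + 32))
            ])
            keep = chunk[annotate_days(chunk, n_probes) == cls][:need]
            rows.append(keep)
            need -= len(keep)
            attempts += 1
            if attempts > MAX_ATTEMPTS:
                raise InputError(
                    f"class {cls} envelope keeps disagreeing with the fuzzy rules"
                )
        X[cls * per_class:(cls + 1) * per_class] = np.concatenate(rows)
    import logging

    logging.getLogger(__name__).info(
        "generated %d sensor days (%d per class, %d probes)", len(X), per_class, n_probes
    )
    return X, y


def dataset_to_frame(X: np.ndarray, y: np.ndarray, n_probes: int) -> pd.DataFrame:
    """Tabular view of a generated dataset (one row per day, flattened vector + label)."""
    cols = []
    for hour in range(HOURS_PER_DAY):
        cols += [f"h{hour:02d}_Tp{p + 1}" for p in range(n_probes)]
        cols += [f"h{hour:02d}_T", f"h{hour:02d}_H"]
    frame = pd.DataFrame(X, columns=cols)
    frame.insert(0, "label", y)
    return frame


# ---------------------------------------------------------------------------
# Audio generation
# ---------------------------------------------------------------------------

AUDIO_CLASS_NAMES = ["queen-loss", "weak", "normal", "early-swarm", "late-swarm"]

#: Characteristic band energies per acoustic class: (low Hz, high Hz, gain).
#: Gains are relative tone amplitudes before peak normalisation; the declared
#: dominant beegram band is used by tests to verify energy locality.
AUDIO_CLASS_BANDS: dict[int, dict] = {
    0: {"name": "queen-loss",  # base hum only, queen tone region silent
        "bands": [(315.0, 350.0, 1.0), (200.0, 230.0, 0.4)], "dominant_bands": {6}},
    1: {"name": "weak",  # energy stuck in the low hunger bands
        "bands": [(107.0, 128.0, 1.0), (129.0, 149.0, 0.6)], "dominant_bands": {0}},
    2: {"name": "normal",  # brood hum plus queen tone at 600-687 Hz
        "bands": [(226.0, 269.0, 1.0), (602.0, 646.0, 0.55), (506.0, 525.0, 0.35)],
        "dominant_bands": {4}},
    3: {"name": "early-swarm",  # 250-300 Hz buzzing with a rising 400-440 Hz edge
        "bands": [(270.0, 312.0, 1.0), (398.0, 441.0, 0.6)], "dominant_bands": {5}},
    4: {"name": "late-swarm",  # strong 400-500 Hz swarming band
        "bands": [(400.0, 500.0, 1.0), (530.0, 545.0, 0.3)], "dominant_bands": {8, 9, 10}},
}

#: White-noise floor amplitude relative to full scale.
NOISE_FLOOR = 0.01


@dataclass
class SynthAudioSpec:
    """Recipe for one synthetic recording."""

    class_id: int
    duration: float = 60.0
    seed: int = 0
    bands: list[tuple[float, float, float]] | None = None
    noise_floor: float = NOISE_FLOOR
    #: Relative amplitudes of the fundamental and its 2 harmonics.
    harmonics: tuple[float, ...] = (1.0, 0.3, 0.15)
    peak: float = 0.8

    def __post_init__(self) -> None:
        if self.class_id not in AUDIO_CLASS_BANDS:
            raise ParameterError(f"unknown audio class {self.class_id}")
        if self.duration < 30.0:
            raise ParameterError("synthetic recordings must be at least 30 s")
        if self.bands is None:
            self.bands = list(AUDIO_CLASS_BANDS[self.class_id]["bands"])


def _band_tones(low: float, high: float) -> list[float]:
    """Tone frequencies placed on STFT row centres spanning [low, high] Hz."""
    from .beegram import FREQ_STEP

    rows = range(int(np.ceil(low / FREQ_STEP)), int(high / FREQ_STEP) + 1)
    tones = [r * FREQ_STEP for r in rows]
    return tones or [(low + high) / 2.0]


def gen_audio(spec: SynthAudioSpec) -> AudioRecording:
    """Synthesise one recording from a class spec: harmonic stacks + noise floor.

    Each configured band contributes tones at the STFT row centres it spans
    (fundamental + 2 weaker harmonics, random phases), so its energy lands
    exactly in the beegram rows the class is meant to light up.  The mix is
    peak-normalised and 8-bit quantised; bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * RATE))
    t = np.arange(n) / RATE
    signal_sum = np.zeros(n)
    for low, high, gain in spec.bands:
        for f0 in _band_tones(low, high):
            for k, h_amp in enumerate(spec.harmonics, start=1):
                phase = rng.uniform(0.0, 2.0 * np.pi)
                signal_sum += gain * h_amp * np.sin(2.0 * np.pi * k * f0 * t + phase)
    peak = np.abs(signal_sum).max()
    if peak > 0:
        signal_sum *= spec.peak / peak
    signal_sum += rng.normal(0.0, 1.0, size=n) * spec.noise_floor
    # device-native 8-bit unsigned quantisation, then back to centred floats
    q = np.clip(np.round(signal_sum * 128.0 + 128.0), 0, 255)
    return AudioRecording(samples=(q - 128.0) / 128.0, rate=RATE)


def gen_audio_class(class_id: int, duration: float = 60.0, seed: int = 0) -> AudioRecording:
    """Convenience wrapper: default spec for one acoustic class."""
    return gen_audio(SynthAudioSpec(class_id=class_id, duration=duration, seed=seed))
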