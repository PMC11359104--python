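import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tone_recording():
    """10 s pure tone at 1076.7 Hz (an exact STFT row centre), unit amplitude."""
    from hivesense.audio import RATE, AudioRecording

    t = np.arange(10 * RATE) / RATE
    return AudioRecording(samples=0.5 * np.sin(2 * np.pi * 1076.66015625 * t), rate=RATE)


@pytest.fixture(scope="session")
def late_swarm_recording():
    from hivesense import gen_audio_class

    return gen_audio_class(4, duration=60.0, seed=11)


@pytest.fixture(scope="session")
def small_sensor_dataset():
    """Small balanced fuzzy-annotated dataset (4 probes): 200 days per class."""
    from hivesense import gen_dataset

    return gen_dataset(per_class=200, n_probes=4, seed=5)


def constant_day(probe_temp, lid_temp, humidity, n_probes=2):
    """A sensor day of constant readings."""
    from hivesense import SensorBatch

    values = np.empty((24, n_probes + 2))
    values[:, :n_probes] = probe_temp
    values[:, n_probes] = lid_temp
    values[:, n_probes + 1] = humidity
    return SensorBatch(values=values, n_probes=n_probes)
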