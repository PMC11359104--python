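"""Fuzzy annotation of in-hive temperature/humidity sensor batches.

Hourly readings from 1-6 brood-frame temperature probes plus a lid
temperature/humidity sensor are condensed to daily means and classified into
five colony-condition classes:

* 0 ``abiotic-cold``        - lid below freezing, probe means below 10 degC
* 1 ``disease-incubation``  - cool and very humid (varroa/nosema-favourable)
* 2 ``normal``              - brood nest at 30-37 degC, 30-80 %RH
* 3 ``abiotic-hot``         - lid above ~42 degC, thermoregulation failing
* 4 ``outlier``             - physically impossible readings (broken probes)

Temperature and humidity readings are first mapped to linguistic-set
confidences by bounded-sigmoid, triangular-sigmoid and Gaussian membership
functions, then combined through a 12-rule Mamdani-style table (min t-norm,
max aggregation) with +/-25 % rule-influence modifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ShapeError

LN3 = float(np.log(3.0))

CLASS_NAMES = ["abiotic-cold", "disease-incubation", "normal", "abiotic-hot", "outlier"]
N_CLASSES = 5
OUTLIER_CLASS = 4

#: Physical plausibility bounds; anything outside is gated straight to class 4.
TEMP_RANGE = (-20.0, 60.0)
HUMIDITY_RANGE = (0.0, 100.0)

#: Membership parameters: (xlow, xhigh) for sigmoids, (xlow, xcenter, xhigh)
#: for triangular forms, (x0, b) for the Gaussian humidity-normal set.
TEMP_SETS = {
    "cold": (0.0, 10.0),          # inverse bounded sigmoid
    "disease": (10.0, 15.0, 28.0),
    "normal": (15.0, 32.0, 38.0),
    "hot": (38.0, 42.0),
}
HUMIDITY_SETS = {
    "dry": (0.0, 30.0),           # inverse bounded sigmoid
    "normal": (40.0, 0.004),      # Gaussian (x0, b)
    "wet": (70.0, 85.0),
}

#: The rule table: (temperature set, humidity set) -> (class id, influence).
#: "plus"/"minus" rules carry 25 % more/less influence.
RULES: list[tuple[str, str, int, float]] = [
    ("cold", "dry", 0, 0.75),
    ("cold", "normal", 0, 1.0),
    ("cold", "wet", 0, 1.25),
    ("disease", "dry", 2, 1.0),
    ("disease", "normal", 1, 1.0),
    ("disease", "wet", 1, 1.25),
    ("normal", "dry", 2, 1.0),
    ("normal", "normal", 2, 1.25),
    ("normal", "wet", 1, 0.75),
    ("hot", "dry", 3, 1.25),
    ("hot", "normal", 3, 1.0),
    ("hot", "wet", 2, 0.75),
]


@dataclass(frozen=True)
class MembershipParams:
    """Parameters of one membership function."""

    xlow: float = 0.0
    xhigh: float = 1.0
    xcenter: float | None = None
    x0: float = 40.0
    b: float = 0.004

    def __post_init__(self) -> None:
        if self.xlow >= self.xhigh:
            raise ParameterError(f"xlow ({self.xlow}) must be below xhigh ({self.xhigh})")
        if self.xcenter is not None and not self.xlow < self.xcenter < self.xhigh:
            raise ParameterError("triangular form needs xlow < xcenter < xhigh")
        if self.b <= 0:
            raise ParameterError("Gaussian steepness b must be positive")


def bounded_sigmoid(x, params: MembershipParams | tuple[float, float]):
    """Sigmoid pinned to 0.1 at ``xlow``, 0.5 at the midpoint, 0.9 at ``xhigh``.

    bs(x) = 1 / (1 + 9 * exp(-4 ln3 (x - xlow) / (xhigh - xlow)))
    """
    if isinstance(params, tuple):
        params = MembershipParams(xlow=params[0], xhigh=params[1])
    x = np.asarray(x, dtype=np.float64)
    z = -4.0 * LN3 * (x - params.xlow) / (params.xhigh - params.xlow)
    return 1.0 / (1.0 + 9.0 * np.exp(np.clip(z, -700.0, 700.0)))


def triangular_sigmoid(x, params: MembershipParams | tuple[float, float, float]):
    """Unimodal form: rising bounded sigmoid up to ``xcenter``, falling beyond.

    Peaks at ~0.9 at ``xcenter`` and decays to ~0.1 at both bounds.
    """
    if isinstance(params, tuple):
        params = MembershipParams(xlow=params[0], xcenter=params[1], xhigh=params[2])
    if params.xcenter is None:
        raise ParameterError("triangular form needs xcenter")
    x = np.asarray(x, dtype=np.float64)
    rising = bounded_sigmoid(x, (params.xlow, params.xcenter))
    falling = 1.0 - bounded_sigmoid(x, (params.xcenter, params.xhigh))
    return np.where(x <= params.xcenter, rising, falling)


def gaussian_membership(x, x0: float = 40.0, b: float = 0.004):
    """Gaussian set exp(-b (x - x0)^2), peaking at 1 at ``x0``."""
    if b <= 0:
        raise ParameterError("Gaussian steepness b must be positive")
    x = np.asarray(x, dtype=np.float64)
    return np.exp(-b * (x - x0) ** 2)


@dataclass
class FuzzyState:
    """Per-set confidences for one (temperature, humidity) reading."""

    temperature: dict[str, float]
    humidity: dict[str, float]


@dataclass
class ClassLabel:
    """A condition class with the winning rule activation as confidence."""

    id: int
    name: str = ""
    confidence: float = 0.0
    activations: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.id not in range(N_CLASSES):
            raise ParameterError(f"class id must be 0-{N_CLASSES - 1}, got {self.id}")
        if not self.name:
            self.name = CLASS_NAMES[self.id]


def fuzzify(T, H) -> FuzzyState:
    """Map a temperature (degC) and humidity (%RH) reading to set confidences."""
    temp = {
        "cold": 1.0 - bounded_sigmoid(T, TEMP_SETS["cold"]),
        "disease": triangular_sigmoid(T, TEMP_SETS["disease"]),
        "normal": triangular_sigmoid(T, TEMP_SETS["normal"]),
        "hot": bounded_sigmoid(T, TEMP_SETS["hot"]),
    }
    hum = {
        "dry": 1.0 - bounded_sigmoid(H, HUMIDITY_SETS["dry"]),
        "normal": gaussian_membership(H, *HUMIDITY_SETS["normal"]),
        "wet": bounded_sigmoid(H, HUMIDITY_SETS["wet"]),
    }
    to_f = lambda d: {k: float(v) for k, v in d.items()}
    if np.ndim(T) == 0 and np.ndim(H) == 0:
        return FuzzyState(temperature=to_f(temp), humidity=to_f(hum))
    return FuzzyState(temperature=temp, humidity=hum)


def _class_activations(state: FuzzyState) -> np.ndarray:
    """Max-aggregated rule activations per class (vectorised over readings)."""
    shape = np.broadcast_shapes(
        np.shape(state.temperature["cold"]), np.shape(state.humidity["dry"])
    )
    acts = np.zeros((N_CLASSES,) + shape)
    for tset, hset, cls, influence in RULES:
        a = influence * np.minimum(state.temperature[tset], state.humidity[hset])
        acts[cls] = np.maximum(acts[cls], a)
    return acts


def classify(state: FuzzyState, T: float, H: float) -> ClassLabel:
    """Argmax class over the 12-rule table; out-of-range readings go to class 4."""
    if not (np.isfinite(T) and np.isfinite(H)):
        return ClassLabel(id=OUTLIER_CLASS, confidence=1.0)
    if not (TEMP_RANGE[0] <= T <= TEMP_RANGE[1] and HUMIDITY_RANGE[0] <= H <= HUMIDITY_RANGE[1]):
        return ClassLabel(id=OUTLIER_CLASS, confidence=1.0)
    acts = _class_activations(state)
    winner = int(np.argmax(acts))
    return ClassLabel(
        id=winner,
        confidence=float(np.clip(acts[winner], 0.0, 1.0)),
        activations={i: float(a) for i, a in enumerate(acts)},
    )


def classify_reading(T: float, H: float) -> ClassLabel:
    """Fuzzify and classify a single (T, H) reading."""
    return classify(fuzzify(T, H), T, H)


# ---------------------------------------------------------------------------
# Daily sensor batches
# ---------------------------------------------------------------------------

HOURS_PER_DAY = 24
MIN_PROBES, MAX_PROBES = 1, 6
#: Valid flattened batch lengths: 24 * (n_probes + 2) for 1-6 probes.
STRAND_SIZES = tuple(HOURS_PER_DAY * (p + 2) for p in range(MIN_PROBES, MAX_PROBES + 1))


@dataclass
class SensorBatch:
    """One day of hourly (probe temps..., lid temperature, humidity) tuples.

    ``values`` has shape (24, n_probes + 2); ``flatten()`` yields the
    strand-input vector in hour-major order (Tp1..Tpp, T, H per hour).
    """

    values: np.ndarray
    n_probes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not MIN_PROBES <= self.n_probes <= MAX_PROBES:
            raise ParameterError(f"n_probes must be {MIN_PROBES}-{MAX_PROBES}, got {self.n_probes}")
        if self.values.shape != (HOURS_PER_DAY, self.n_probes + 2):
            raise ShapeError(
                f"sensor batch must be ({HOURS_PER_DAY}, {self.n_probes + 2}), "
                f"got {self.values.shape}"
            )

    @property
    def probe_temps(self) -> np.ndarray:
        return self.values[:, : self.n_probes]

    @property
    def lid_temp(self) -> np.ndarray:
        return self.values[:, self.n_probes]

    @property
    def humidity(self) -> np.ndarray:
        return self.values[:, self.n_probes + 1]

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)

    @classmethod
    def from_vector(cls, vector: np.ndarray, n_probes: int) -> "SensorBatch":
        vector = np.asarray(vector, dtype=np.float64).reshape(-1)
        width = n_probes + 2
        if vector.size != HOURS_PER_DAY * width:
            raise ShapeError(
                f"vector of length {vector.size} does not match {n_probes} probes "
                f"(expected {HOURS_PER_DAY * width})"
            )
        return cls(values=vector.reshape(HOURS_PER_DAY, width), n_probes=n_probes)


def _out_of_range(batch: SensorBatch) -> bool:
    temps = batch.values[:, : batch.n_probes + 1]
    hum = batch.humidity
    return bool(
        np.any(~np.isfinite(batch.values))
        or np.any(temps < TEMP_RANGE[0]) or np.any(temps > TEMP_RANGE[1])
        or np.any(hum < HUMIDITY_RANGE[0]) or np.any(hum > HUMIDITY_RANGE[1])
    )


def annotate_day(batch: SensorBatch) -> ClassLabel:
    """Classify a full sensor day.

    Daily means are taken per signal; the fuzzified temperature is the blend
    (mean probe temperature + mean lid temperature) / 2.  Any single raw
    reading outside the physical sensor range forces the outlier class.
    """
    if _out_of_range(batch):
        return ClassLabel(id=OUTLIER_CLASS, confidence=1.0)
    t_blend = 0.5 * (batch.probe_temps.mean() + batch.lid_temp.mean())
    h_mean = float(batch.humidity.mean())
    return classify_reading(float(t_blend), h_mean)


def annotate_days(X: np.ndarray, n_probes: int) -> np.ndarray:
    """Vectorised :func:`annotate_day` over rows of a (n_days, 24*(p+2)) matrix."""
    X = np.asarray(X, dtype=np.float64)
    width = n_probes + 2
    days = X.reshape(len(X), HOURS_PER_DAY, width)
    temps = days[:, :, : n_probes + 1]
    hum = days[:, :, n_probes + 1]
    bad = (
        ~np.isfinite(days).all(axis=(1, 2))
        | (temps < TEMP_RANGE[0]).any(axis=(1, 2))
        | (temps > TEMP_RANGE[1]).any(axis=(1, 2))
        | (hum < HUMIDITY_RANGE[0]).any(axis=1)
        | (hum > HUMIDITY_RANGE[1]).any(axis=1)
    )
    t_blend = 0.5 * (days[:, :, :n_probes].mean(axis=(1, 2)) + days[:, :, n_probes].mean(axis=1))
    h_mean = hum.mean(axis=1)
    acts = _class_activations(fuzzify(t_blend, h_mean))
    labels = np.argmax(acts, axis=0)
    labels[bad] = OUTLIER_CLASS
    return labels.astype(np.int64)
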