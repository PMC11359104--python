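"""Beegram extraction and the five apiary condition measures.

The *beegram* is a 16-element vector of mean spectral magnitudes over fixed
low-frequency bands (roughly 107-687 Hz, the region where colony sound
carries information) of the 224 x 224 mean response matrix.  Five scalar
measures are derived from it, each tracking one colony condition:

* ``Bh`` hunger        - mean of bands 0-1 (107-149 Hz)
* ``Bg`` growth        - mean of bands 2-7
* ``Qt`` queen tone    - max of bands 11-12 plus band 15 (602-687 Hz piping)
* ``Th`` thermal stress - band 7 (wing-fanning region)
* ``Sw`` swarming      - 3/4 max of bands 8-10 (~400-500 Hz) + 1/4 max of bands 11-14

Each measure has calibrated critical limits; a flag is raised when the limit
is crossed.  Measures are evaluated on the unit-normalised mean response
matrix (the scale the limits were calibrated on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import CROP, MeanResponseMatrix, N_FFT, RATE, normalize_unit
from .errors import ConfigError, ShapeError

#: Hz covered by one frequency row of the mean response matrix.
FREQ_STEP = RATE / N_FFT
#: The beegram reads only the first 31 frequency rows (0-~646 Hz) of A.
MAX_ROW = 30

N_BANDS = 16

#: Critical-event limits: measure -> (low, high); None means unbounded on that side.
CRITICAL_LIMITS: dict[str, tuple[float | None, float | None]] = {
    "Bh": (0.3, 1.8),   # hungry when <= 0.3, agitated/overfull when > 1.8
    "Bg": (0.1, None),  # no growth activity when <= 0.1
    "Qt": (0.3, 0.8),   # queen missing when <= 0.3, piping/stress when > 0.8
    "Th": (None, 0.5),  # thermal stress when > 0.5
    "Sw": (None, 0.7),  # swarming build-up when > 0.7
}


@dataclass(frozen=True)
class Band:
    """One beegram band: a frequency range and the matrix rows covering it."""

    low_hz: float
    high_hz: float
    rows: tuple[int, ...]


@dataclass
class BandTable:
    """Ordered, non-overlapping 16-band partition of the low-frequency rows."""

    bands: list[Band]

    def __post_init__(self) -> None:
        if len(self.bands) != N_BANDS:
            raise ConfigError(f"band table needs {N_BANDS} bands, got {len(self.bands)}")
        seen: set[int] = set()
        prev_high = -np.inf
        for i, band in enumerate(self.bands):
            if band.low_hz >= band.high_hz:
                raise ConfigError(f"band {i} has an empty frequency range")
            if band.low_hz < prev_high:
                raise ConfigError(f"band {i} overlaps its predecessor")
            prev_high = band.high_hz
            for r in band.rows:
                if not 0 <= r <= MAX_ROW:
                    raise ConfigError(f"band {i} row {r} outside the first {MAX_ROW + 1} rows")
                if r in seen:
                    raise ConfigError(f"row {r} assigned to two bands")
                seen.add(r)

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, i: int) -> Band:
        return self.bands[i]


def _rows_in_range(low_hz: float, high_hz: float) -> tuple[int, ...]:
    """Rows whose centre frequency (row * FREQ_STEP) lies inside [low, high] Hz."""
    rows = [r for r in range(MAX_ROW + 1) if low_hz <= r * FREQ_STEP <= high_hz]
    return tuple(rows)


def default_band_table() -> BandTable:
    """The default 16-band table.

    Bands 0, 1 and 15 carry the calibrated frequency ranges 107-128,
    129-149 and 602-687 Hz; the 13 intermediate bands form a contiguous,
    near-uniform partition of the rows between them.  Row assignment follows
    centre frequency, capped at the 31st row of the matrix.
    """
    b0 = Band(107.0, 128.0, _rows_in_range(107.0, 128.0))
    b1 = Band(129.0, 149.0, _rows_in_range(129.0, 149.0))
    b15 = Band(602.0, 687.0, _rows_in_range(602.0, 687.0))
    first_mid = b1.rows[-1] + 1
    last_mid = b15.rows[0] - 1
    chunks = np.array_split(np.arange(first_mid, last_mid + 1), N_BANDS - 3)
    mids = []
    prev_high = b1.high_hz  # chain edges so the printed ranges stay authoritative
    for chunk in chunks:
        high = min((chunk[-1] + 0.5) * FREQ_STEP, b15.low_hz)
        mids.append(Band(low_hz=prev_high, high_hz=high, rows=tuple(int(r) for r in chunk)))
        prev_high = high
    return BandTable(bands=[b0, b1, *mids, b15])


@dataclass
class BeegramVector:
    """The 16 band-mean magnitudes b[0]..b[15] with the table that produced them."""

    b: np.ndarray
    band_table: BandTable = field(default_factory=default_band_table)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.b.shape != (N_BANDS,):
            raise ShapeError(f"beegram vector must have {N_BANDS} elements, got {self.b.shape}")
        if not np.all(np.isfinite(self.b)) or np.any(self.b < 0):
            raise ShapeError("beegram elements must be finite and non-negative")


@dataclass
class BeegramMeasures:
    """The five condition measures and their critical-event flags."""

    Bh: float
    Bg: float
    Qt: float
    Th: float
    Sw: float
    flags: dict[str, bool] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "Bh": self.Bh, "Bg": self.Bg, "Qt": self.Qt,
            "Th": self.Th, "Sw": self.Sw, "flags": dict(self.flags),
        }


def extract_beegram(
    A: MeanResponseMatrix | np.ndarray,
    table: BandTable | None = None,
    normalize: bool = True,
) -> BeegramVector:
    """Mean magnitude of ``A`` over each band's rows and all time columns.

    By default the matrix is unit-normalised first, matching the scale the
    critical limits were calibrated on.
    """
    table = table or default_band_table()
    arr = A.A if isinstance(A, MeanResponseMatrix) else np.asarray(A, dtype=np.float64)
    if arr.shape != (CROP, CROP):
        raise ShapeError(f"expected a {(CROP, CROP)} matrix, got {arr.shape}")
    if normalize:
        arr = normalize_unit(arr)
    values = np.array([np.abs(arr[list(band.rows), :]).mean() for band in table])
    return BeegramVector(b=values, band_table=table)


def _flag(name: str, value: float) -> bool:
    low, high = CRITICAL_LIMITS[name]
    return (low is not None and value <= low) or (high is not None and value > high)


def compute_measures(b: BeegramVector | np.ndarray) -> BeegramMeasures:
    """Evaluate the five condition measures and their critical flags."""
    v = np.abs(b.b if isinstance(b, BeegramVector) else np.asarray(b, dtype=np.float64))
    if v.shape != (N_BANDS,):
        raise ShapeError(f"beegram vector must have {N_BANDS} elements, got {v.shape}")
    measures = BeegramMeasures(
        Bh=(v[0] + v[1]) / 2.0,
        Bg=v[2:8].sum() / 6.0,
        Qt=max(v[11], v[12]) + v[15],
        Th=v[7],
        Sw=0.75 * v[8:11].max() + 0.25 * v[11:15].max(),
    )
    measures.flags = {name: _flag(name, getattr(measures, name)) for name in CRITICAL_LIMITS}
    return measures
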