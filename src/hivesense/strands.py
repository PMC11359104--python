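"""The stranded dense classifier for daily sensor batches.

One small fully connected network ("strand") exists per flattened batch size
72, 96, 120, 144, 168, 192 — i.e. per probe count 1-6, since a day holds
24 hourly tuples of (probes..., lid temperature, humidity).  At inference
time a vector is routed to the strand matching its length.  Strands train on
fuzzy-annotated data with the shared recipe (Adam, cross-entropy, L1 0.005
on dense weights, 100 epochs of batch-64 updates).

Default topology: input -> h1 -> 32 -> 5, with h1 equal to the input size
for inputs up to 120 and 256 for the larger strands.  These widths reproduce
the published trainable-parameter counts (12,581 for the 96-strand, 45,509
for the 144-strand).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError, RoutingError, ShapeError, StateError
from .fuzzy import (
    CLASS_NAMES,
    HOURS_PER_DAY,
    MAX_PROBES,
    MIN_PROBES,
    N_CLASSES,
    STRAND_SIZES,
    ClassLabel,
)
from .metrics import ConfusionMatrix, EpochMetrics, accuracy
from .nn_core import Dense, Network, ReLU, TrainConfig, train_network


def strand_input_size(n_probes: int) -> int:
    """Flattened daily batch length: 24 hourly (probes + lid T + humidity) tuples."""
    if not MIN_PROBES <= n_probes <= MAX_PROBES:
        raise ParameterError(f"n_probes must be {MIN_PROBES}-{MAX_PROBES}, got {n_probes}")
    return HOURS_PER_DAY * (n_probes + 2)


def default_hidden(input_size: int) -> tuple[int, int]:
    """Hidden widths reproducing the published strand parameter counts."""
    return (input_size if input_size <= 120 else 256, 32)


@dataclass
class StrandSpec:
    """Architecture of one strand."""

    input_size: int
    hidden: tuple[int, ...] = ()
    n_classes: int = N_CLASSES
    l1_lambda: float = 0.005

    def __post_init__(self) -> None:
        if self.input_size not in STRAND_SIZES:
            raise ParameterError(
                f"input_size must be one of {STRAND_SIZES}, got {self.input_size}"
            )
        if not self.hidden:
            self.hidden = default_hidden(self.input_size)

    @property
    def n_probes(self) -> int:
        return self.input_size // HOURS_PER_DAY - 2

    @property
    def n_params(self) -> int:
        sizes = (self.input_size, *self.hidden, self.n_classes)
        return int(sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:])))


class StrandModel:
    """One trained (or trainable) strand: a dense network plus its spec."""

    def __init__(self, spec: StrandSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers = []
        sizes = (spec.input_size, *spec.hidden)
        for a, b in zip(sizes[:-1], sizes[1:]):
            layers += [Dense(a, b, rng), ReLU()]
        layers.append(Dense(sizes[-1], spec.n_classes, rng))
        self.net = Network(layers, n_classes=spec.n_classes)
        self.holdout_accuracy: float | None = None
        self.holdout_confusion: ConfusionMatrix | None = None
        self.metrics: EpochMetrics | None = None

    @property
    def n_params(self) -> int:
        return self.net.n_params

    @property
    def trained(self) -> bool:
        return self.net.trained

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.net.trained:
            raise StateError("strand has not been trained")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.spec.input_size:
            raise ShapeError(
                f"vector length {X.shape[1]} does not match strand input {self.spec.input_size}"
            )
        return self.net.predict_proba(X)


def build_strand(n_probes: int, seed: int = 0, hidden: tuple[int, ...] = ()) -> StrandModel:
    """Construct the default strand for a device with ``n_probes`` probes."""
    spec = StrandSpec(input_size=strand_input_size(n_probes), hidden=hidden)
    return StrandModel(spec, seed=seed)


def train_strand(
    model: StrandModel,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[StrandModel, EpochMetrics]:
    """Train a strand on labelled daily vectors with the shared recipe.

    The dataset is split 80/20 into training and held-out parts (seeded
    shuffle); per-epoch validation metrics come from 10 % of the training
    part; the held-out accuracy and confusion matrix are stored on the model.
    """
    config = config or TrainConfig()
    config.l1_lambda = model.spec.l1_lambda if config.l1_lambda is None else config.l1_lambda
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(X) == 0:
        raise InputError("empty dataset")
    if X.ndim != 2 or X.shape[1] != model.spec.input_size:
        raise ShapeError(
            f"dataset vectors of length {X.shape[-1]} do not match strand input "
            f"{model.spec.input_size}"
        )
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(X))
    n_train = int(round(config.train_fraction * len(X)))
    tr, te = perm[:n_train], perm[n_train:]
    metrics = train_network(model.net, X[tr], y[tr], config)
    model.metrics = metrics
    if len(te):
        pred = model.net.predict(X[te])
        cm = ConfusionMatrix.from_predictions(y[te], pred, model.spec.n_classes)
        model.holdout_confusion = cm
        model.holdout_accuracy = 100.0 * accuracy(cm)
    return model, metrics


class StrandedClassifier:
    """A bundle of strands routed by input-vector length."""

    def __init__(self, strands: dict[int, StrandModel] | None = None):
        self.strands = dict(strands or {})

    def add(self, model: StrandModel) -> None:
        self.strands[model.spec.input_size] = model

    def route(self, length: int) -> StrandModel:
        if length not in STRAND_SIZES:
            raise RoutingError(
                f"vector length {length} matches no strand (valid: {STRAND_SIZES})"
            )
        if length not in self.strands:
            raise StateError(f"no trained strand registered for input size {length}")
        return self.strands[length]

    def infer(self, vector: np.ndarray) -> tuple[ClassLabel, np.ndarray]:
        """Route a flattened daily vector and return (label, class probabilities)."""
        vector = np.asarray(vector, dtype=np.float64).reshape(-1)
        model = self.route(vector.size)
        proba = model.predict_proba(vector)[0]
        winner = int(np.argmax(proba))
        return (
            ClassLabel(id=winner, name=CLASS_NAMES[winner], confidence=float(proba[winner])),
            proba,
        )

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | os.PathLike) -> None:
        """Write each strand as a .npz weight archive with a JSON sidecar."""
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        for size, model in self.strands.items():
            base = os.path.join(directory, f"strand_{size}")
            model.net.save_weights(base + ".npz")
            sidecar = {
                "input_size": size,
                "hidden": list(model.spec.hidden),
                "n_classes": model.spec.n_classes,
                "l1_lambda": model.spec.l1_lambda,
                "holdout_accuracy": model.holdout_accuracy,
            }
            with open(base + ".json", "w") as fh:
                json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "StrandedClassifier":
        directory = os.fspath(directory)
        bundle = cls()
        names = sorted(
            n for n in os.listdir(directory)
            if n.endswith(".json") and n.startswith("strand_")
            and os.path.exists(os.path.join(directory, n[:-5] + ".npz"))
        )
        if not names:
            raise StateError(f"no strand checkpoints found in {directory}")
        for name in names:
            with open(os.path.join(directory, name)) as fh:
                sidecar = json.load(fh)
            spec = StrandSpec(
                input_size=sidecar["input_size"],
                hidden=tuple(sidecar["hidden"]),
                n_classes=sidecar["n_classes"],
                l1_lambda=sidecar["l1_lambda"],
            )
            model = StrandModel(spec)
            model.net.load_weights(os.path.join(directory, name[:-5] + ".npz"))
            model.holdout_accuracy = sidecar.get("holdout_accuracy")
            bundle.add(model)
        return bundle
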