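"""Strand construction, sizing, training behaviour, and routed inference."""

import numpy as np
import pytest

import hivesense as hs
from hivesense.strands import StrandSpec, default_hidden, strand_input_size


class TestSizing:
    @pytest.mark.parametrize("n_probes,size", [(1, 72), (2, 96), (3, 120), (4, 144), (5, 168), (6, 192)])
    def test_input_size_law(self, n_probes, size):
        assert strand_input_size(n_probes) == size

    def test_96_strand_parameter_count(self):
        model = hs.build_strand(2)
        assert model.n_params == 12_581
        assert round(model.n_params / 1e6, 3) == 0.013

    def test_144_strand_parameter_count(self):
        model = hs.build_strand(4)
        assert model.n_params == 45_509
        assert round(model.n_params / 1e6, 3) == 0.046

    def test_spec_count_matches_built_network(self):
        for p in range(1, 7):
            spec = StrandSpec(input_size=strand_input_size(p))
            assert hs.build_strand(p).n_params == spec.n_params

    def test_hidden_width_switch(self):
        assert default_hidden(120) == (120, 32)
        assert default_hidden(144) == (256, 32)

    def test_bad_probe_count_rejected(self):
        with pytest.raises(hs.ParameterError):
            hs.build_strand(7)


@pytest.fixture(scope="module")
def trained_small_strand(small_sensor_dataset):
    X, y = small_sensor_dataset
    model = hs.build_strand(4, seed=0)
    cfg = hs.TrainConfig(epochs=12, seed=0)
    model, metrics = hs.train_strand(model, X, y, cfg)
    return model, metrics, (X, y)


class TestTraining:
    def test_recovers_classes_on_small_dataset(self, trained_small_strand):
        model, metrics, _ = trained_small_strand
        assert model.holdout_accuracy is not None and model.holdout_accuracy > 80.0
        assert len(metrics.accuracy) == 12

    def test_l1_penalty_shrinks_weights(self, small_sensor_dataset):
        X, y = small_sensor_dataset
        norms = {}
        for lam in (0.0, 0.005):
            model = hs.build_strand(4, seed=0)
            cfg = hs.TrainConfig(epochs=6, seed=0, l1_lambda=lam)
            hs.train_strand(model, X, y, cfg)
            norms[lam] = model.net.l1_weight_norm()
        assert norms[0.005] < norms[0.0]

    def test_single_class_dataset_warns(self, caplog):
        X = np.random.default_rng(0).random((100, 96))
        y = np.zeros(100, dtype=int)
        model = hs.build_strand(2, seed=0)
        with caplog.at_level("WARNING"):
            model, metrics = hs.train_strand(model, X, y, hs.TrainConfig(epochs=10, seed=0))
        assert metrics.accuracy[-1] == 100.0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_size_mismatch_rejected(self, small_sensor_dataset):
        X, y = small_sensor_dataset
        model = hs.build_strand(2)
        with pytest.raises(hs.ShapeError):
            hs.train_strand(model, X, y, hs.TrainConfig(epochs=1))

    def test_empty_dataset_rejected(self):
        with pytest.raises(hs.InputError):
            hs.train_strand(hs.build_strand(2), np.empty((0, 96)), np.empty(0, dtype=int))


class TestInference:
    def test_routing_by_length(self, trained_small_strand):
        model, _, (X, y) = trained_small_strand
        bundle = hs.StrandedClassifier()
        bundle.add(model)
        label, proba = bundle.infer(X[0])
        assert label.id in range(5)
        assert proba.shape == (5,)
        assert np.isclose(proba.sum(), 1.0, atol=1e-6)

    def test_unknown_length_raises_routing_error(self, trained_small_strand):
        model, _, _ = trained_small_strand
        bundle = hs.StrandedClassifier({model.spec.input_size: model})
        with pytest.raises(hs.RoutingError):
            bundle.infer(np.zeros(100))

    def test_untrained_strand_raises_state_error(self):
        bundle = hs.StrandedClassifier()
        bundle.add(hs.build_strand(2))
        with pytest.raises(hs.StateError):
            bundle.infer(np.zeros(96))
        with pytest.raises(hs.StateError):
            bundle.infer(np.zeros(144))  # never registered at all

    def test_inference_deterministic(self, trained_small_strand):
        model, _, (X, _) = trained_small_strand
        p1 = model.predict_proba(X[:10])
        p2 = model.predict_proba(X[:10])
        np.testing.assert_array_equal(p1, p2)

    def test_mostly_correct_on_training_distribution(self, trained_small_strand):
        model, _, (X, y) = trained_small_strand
        pred = np.argmax(model.predict_proba(X), axis=1)
        assert (pred == y).mean() > 0.8


class TestPersistence:
    def test_save_load_roundtrip(self, trained_small_strand, tmp_path):
        model, _, (X, _) = trained_small_strand
        bundle = hs.StrandedClassifier({model.spec.input_size: model})
        bundle.save(tmp_path)
        loaded = hs.StrandedClassifier.load(tmp_path)
        np.testing.assert_allclose(
            loaded.strands[144].predict_proba(X[:5]), model.predict_proba(X[:5]), atol=1e-6
        )

    def test_load_empty_directory_raises(self, tmp_path):
        with pytest.raises(hs.StateError):
            hs.StrandedClassifier.load(tmp_path)
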