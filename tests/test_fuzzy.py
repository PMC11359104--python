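"""Fuzzy membership functions, the rule engine, and daily annotation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hivesense as hs
from hivesense import fuzzy

from conftest import constant_day

ALL_SIGMOID_SETS = [
    ("temperature cold", (0.0, 10.0)),
    ("temperature hot", (38.0, 42.0)),
    ("humidity dry", (0.0, 30.0)),
    ("humidity wet", (70.0, 85.0)),
]


class TestBoundedSigmoid:
    @pytest.mark.parametrize("name,bounds", ALL_SIGMOID_SETS)
    def test_anchor_points(self, name, bounds):
        lo, hi = bounds
        assert fuzzy.bounded_sigmoid(lo, bounds) == pytest.approx(0.1, abs=1e-12)
        assert fuzzy.bounded_sigmoid((lo + hi) / 2, bounds) == pytest.approx(0.5, abs=1e-12)
        assert fuzzy.bounded_sigmoid(hi, bounds) == pytest.approx(0.9, abs=1e-12)

    def test_strictly_increasing(self):
        xs = np.linspace(-30, 60, 400)
        ys = fuzzy.bounded_sigmoid(xs, (0.0, 10.0))
        assert np.all(np.diff(ys) > 0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(hs.ParameterError):
            fuzzy.bounded_sigmoid(5.0, fuzzy.MembershipParams(xlow=10.0, xhigh=10.0))


class TestTriangularSigmoid:
    @pytest.mark.parametrize("params", [(10.0, 15.0, 28.0), (15.0, 32.0, 38.0)])
    def test_peak_and_feet(self, params):
        lo, mid, hi = params
        assert fuzzy.triangular_sigmoid(mid, params) == pytest.approx(0.9, abs=1e-12)
        assert fuzzy.triangular_sigmoid(lo, params) == pytest.approx(0.1, abs=1e-12)
        assert fuzzy.triangular_sigmoid(hi, params) == pytest.approx(0.1, abs=1e-12)

    def test_unimodal(self):
        xs = np.linspace(5, 35, 500)
        ys = np.asarray(fuzzy.triangular_sigmoid(xs, (10.0, 15.0, 28.0)))
        peak = int(np.argmax(ys))
        assert np.all(np.diff(ys[:peak]) >= 0) and np.all(np.diff(ys[peak:]) <= 0)

    def test_bad_ordering_rejected(self):
        with pytest.raises(hs.ParameterError):
            fuzzy.triangular_sigmoid(5.0, (10.0, 9.0, 28.0))


class TestGaussian:
    def test_values(self):
        assert fuzzy.gaussian_membership(40.0) == 1.0
        assert fuzzy.gaussian_membership(0.0) == pytest.approx(np.exp(-6.4), rel=1e-9)
        assert fuzzy.gaussian_membership(65.0) == pytest.approx(np.exp(-2.5), rel=1e-9)

    def test_symmetry_about_peak(self):
        d = np.linspace(0, 50, 101)
        np.testing.assert_allclose(
            fuzzy.gaussian_membership(40.0 + d), fuzzy.gaussian_membership(40.0 - d)
        )


class TestFuzzify:
    def test_cold_midpoint(self):
        assert fuzzy.fuzzify(5.0, 50.0).temperature["cold"] == pytest.approx(0.5, abs=1e-12)

    def test_humidity_normal_peak(self):
        assert fuzzy.fuzzify(20.0, 40.0).humidity["normal"] == 1.0

    def test_wet_midpoint(self):
        assert fuzzy.fuzzify(20.0, 77.5).humidity["wet"] == pytest.approx(0.5, abs=1e-12)

    @given(st.floats(-20, 60), st.floats(0, 100))
    def test_all_memberships_in_unit_interval(self, T, H):
        state = fuzzy.fuzzify(T, H)
        for v in (*state.temperature.values(), *state.humidity.values()):
            assert 0.0 <= v <= 1.0


def brute_force_classify(T, H):
    """Independent rule-table evaluation: explicit memberships, min/max, modifiers."""
    ln3 = np.log(3.0)

    def bs(x, lo, hi):
        return 1.0 / (1.0 + 9.0 * np.exp(-4.0 * ln3 * (x - lo) / (hi - lo)))

    def ts(x, lo, mid, hi):
        return bs(x, lo, mid) if x <= mid else 1.0 - bs(x, mid, hi)

    t = {"cold": 1 - bs(T, 0, 10), "disease": ts(T, 10, 15, 28),
         "normal": ts(T, 15, 32, 38), "hot": bs(T, 38, 42)}
    h = {"dry": 1 - bs(H, 0, 30), "normal": np.exp(-0.004 * (H - 40.0) ** 2),
         "wet": bs(H, 70, 85)}
    rules = [
        ("cold", "dry", 0, 0.75), ("cold", "normal", 0, 1.0), ("cold", "wet", 0, 1.25),
        ("disease", "dry", 2, 1.0), ("disease", "normal", 1, 1.0), ("disease", "wet", 1, 1.25),
        ("normal", "dry", 2, 1.0), ("normal", "normal", 2, 1.25), ("normal", "wet", 1, 0.75),
        ("hot", "dry", 3, 1.25), ("hot", "normal", 3, 1.0), ("hot", "wet", 2, 0.75),
    ]
    best = [0.0] * 4
    for ts_name, hs_name, cls, mod in rules:
        best[cls] = max(best[cls], mod * min(t[ts_name], h[hs_name]))
    return int(np.argmax(best))


class TestClassify:
    @pytest.mark.parametrize("T,H,expected", [
        (34.0, 55.0, 2),   # typical normal brood-nest conditions
        (-5.0, 50.0, 0),   # freezing lid
        (44.0, 50.0, 3),   # overheating
        (15.0, 90.0, 1),   # cool and saturated: disease incubation
    ])
    def test_reference_conditions(self, T, H, expected):
        assert fuzzy.classify_reading(T, H).id == expected

    @pytest.mark.parametrize("T,H", [(-25.0, 50.0), (65.0, 50.0), (30.0, 120.0), (30.0, -5.0)])
    def test_physically_impossible_readings_are_outliers(self, T, H):
        assert fuzzy.classify_reading(T, H).id == 4

    def test_matches_brute_force_on_grid(self):
        Ts = np.linspace(-15, 55, 40)
        Hs = np.linspace(1, 99, 40)
        for T in Ts:
            for H in Hs:
                assert fuzzy.classify_reading(T, H).id == brute_force_classify(T, H)

    def test_confidence_clipped_to_unit(self):
        label = fuzzy.classify_reading(34.0, 42.0)  # plus-rule can activate above 1
        assert 0.0 <= label.confidence <= 1.0

    def test_disease_dominates_when_very_humid(self):
        # sweeping the disease temperature range at 90 %RH keeps class 1 on top
        for T in np.linspace(11, 27, 20):
            assert fuzzy.classify_reading(T, 90.0).id == 1


class TestAnnotateDay:
    def test_normal_day(self):
        assert fuzzy.annotate_day(constant_day(34.0, 33.0, 55.0)).id == 2

    def test_single_broken_reading_forces_outlier(self):
        batch = constant_day(34.0, 33.0, 55.0)
        batch.values[7, 3] = 250.0  # humidity column
        assert fuzzy.annotate_day(batch).id == 4

    def test_cold_day(self):
        assert fuzzy.annotate_day(constant_day(8.0, -2.0, 70.0)).id == 0

    def test_vectorised_annotation_agrees_with_scalar(self):
        rng = np.random.default_rng(9)
        days = []
        for _ in range(50):
            base = rng.uniform(-10, 50, size=3)
            v = np.empty((24, 4))
            v[:, :2] = base[0] + rng.normal(0, 0.5, (24, 2))
            v[:, 2] = base[1] + rng.normal(0, 0.5, 24)
            v[:, 3] = np.clip(base[2] + 40 + rng.normal(0, 2, 24), -10, 130)
            days.append(v.reshape(-1))
        X = np.stack(days)
        vec = fuzzy.annotate_days(X, n_probes=2)
        scalar = [fuzzy.annotate_day(hs.SensorBatch.from_vector(x, 2)).id for x in X]
        np.testing.assert_array_equal(vec, scalar)

    def test_malformed_batch_rejected(self):
        with pytest.raises(hs.ShapeError):
            hs.SensorBatch.from_vector(np.zeros(100), 2)
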