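import dataclasses

import numpy as np
import pytest
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor

from ctloop.condition_space import Scheme, sample_uniform
from ctloop.datasets import Dataset, ExperimentRecord
from ctloop.oracle import OracleParams, calibrate_variance_shares, true_ct
from ctloop.surrogate import (
    ModelRegistry,
    TrainedSurrogate,
    WeightingReport,
    default_registry,
    overfitting_monitor,
    predict_ct,
    train_and_select,
    weighting_factors,
)


def _dataset_from_fn(space, fn, n, seed):
    ds = Dataset(space_id=space.space_id)
    for scheme in sample_uniform(space, n, seed=seed):
        ds.append(ExperimentRecord(scheme=scheme, ct=fn(scheme), conc=1e5))
    return ds


@pytest.fixture
def linear_dataset(mixed_space):
    # ct is exactly linear in the scaled numeric feature
    return _dataset_from_fn(
        mixed_space, lambda s: 28.0 + 4.0 * (s.assignments["B"] - 200.0) / 800.0, 60, 1
    )


class TestSelection:
    def test_linear_model_wins_on_noise_free_linear_data(self, mixed_space, linear_dataset):
        registry = ModelRegistry(
            {
                "linear": lambda seed: LinearRegression(),
                "baseline": lambda seed: DummyRegressor(strategy="mean"),
            }
        )
        surrogate = train_and_select(linear_dataset, mixed_space, registry, seed=0)
        assert surrogate.model_id == "linear"
        assert surrogate.cv_r2 == pytest.approx(1.0, abs=1e-9)

    def test_single_model_registry_is_selected(self, mixed_space, linear_dataset):
        registry = ModelRegistry({"baseline": lambda seed: DummyRegressor(strategy="mean")})
        surrogate = train_and_select(linear_dataset, mixed_space, registry, seed=0)
        assert surrogate.model_id == "baseline"

    def test_degenerate_labels_rejected(self, mixed_space):
        flat = _dataset_from_fn(mixed_space, lambda s: 26.0, 30, 2)
        with pytest.raises(ValueError, match="zero variance"):
            train_and_select(flat, mixed_space, default_registry(), seed=0)

    def test_selection_deterministic_per_seed(self, mixed_space, linear_dataset, fast_registry):
        a = train_and_select(linear_dataset, mixed_space, fast_registry, seed=3)
        b = train_and_select(linear_dataset, mixed_space, fast_registry, seed=3)
        assert a.model_id == b.model_id
        assert a.cv_r2 == b.cv_r2


class TestPrediction:
    def test_interpolating_model_returns_training_label(self, mixed_space, linear_dataset):
        registry = ModelRegistry({"knn1": lambda seed: KNeighborsRegressor(n_neighbors=1)})
        surrogate = train_and_select(linear_dataset, mixed_space, registry, seed=0)
        record = linear_dataset.records[0]
        assert predict_ct(surrogate, [record.scheme])[0] == pytest.approx(record.ct)

    def test_batch_equals_one_by_one(self, mixed_space, linear_dataset, fast_registry):
        surrogate = train_and_select(linear_dataset, mixed_space, fast_registry, seed=0)
        schemes = sample_uniform(mixed_space, 20, seed=5)
        batch = predict_ct(surrogate, schemes)
        single = np.array([predict_ct(surrogate, [s])[0] for s in schemes])
        assert np.allclose(batch, single)

    def test_predictions_finite_on_1000_random_schemes(self, mixed_space, linear_dataset, fast_registry):
        surrogate = train_and_select(linear_dataset, mixed_space, fast_registry, seed=0)
        preds = predict_ct(surrogate, sample_uniform(mixed_space, 1000, seed=6))
        assert np.all(np.isfinite(preds))


class TestOverfittingMonitor:
    def _fake(self, train_mse, cv_mse, rnd):
        return TrainedSurrogate(
            model_id="m",
            model=None,
            space=None,
            cv_r2=0.9,
            cv_r2_folds=[0.9],
            cv_mse=cv_mse,
            train_mse=train_mse,
            training_round=rnd,
        )

    def test_matched_errors_do_not_flag(self):
        history = [self._fake(0.5, 0.5, r) for r in range(1, 4)]
        report = overfitting_monitor(history)
        assert not report["flag"]
        assert len(report["train_mse"]) == 3

    def test_two_consecutive_collapsed_ratios_flag(self):
        history = [self._fake(0.5, 0.5, 1), self._fake(0.01, 1.0, 2), self._fake(0.01, 1.0, 3)]
        report = overfitting_monitor(history)
        assert report["flag"]
        assert report["flagged_rounds"] == [3]

    def test_single_bad_round_is_not_enough(self):
        history = [self._fake(0.5, 0.5, 1), self._fake(0.01, 1.0, 2), self._fake(0.5, 0.5, 3)]
        assert not overfitting_monitor(history)["flag"]

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            overfitting_monitor([])


class TestWeightingFactors:
    def test_single_category_space_gets_weight_one(self):
        from ctloop.condition_space import ConditionCategory, ConditionSpace

        space = ConditionSpace(
            space_id="one",
            categories=(ConditionCategory("x", "categorical", levels=("x0", "x1", "x2")),),
        )
        penalties = {"x0": 0.0, "x1": 1.0, "x2": 2.0}
        ds = _dataset_from_fn(space, lambda s: 26.0 + penalties[s.assignments["x"]], 60, 3)
        surrogate = train_and_select(
            ds, space, ModelRegistry({"knn1": lambda seed: KNeighborsRegressor(n_neighbors=1)}), seed=0
        )
        report = weighting_factors(surrogate, space, probe_n=500, seed=0)
        assert report.weights == {"x": 1.0}

    def test_planted_shares_recovered_from_uniform_training(self, tiny_space):
        oracle = OracleParams(
            space=tiny_space,
            optimum=Scheme(assignments={"a": "a0", "b": "b0", "c": "c0"}),
            level_penalties={
                "a": {"a0": 0.0, "a1": 1.0, "a2": 2.0},
                "b": {"b0": 0.0, "b1": 0.5, "b2": 1.0},
            },
            noise_sigma_auto=0.0,
        )
        oracle = calibrate_variance_shares(oracle, {"a": 0.8, "b": 0.2, "c": 0.0}, mc_n=20_000, seed=1)
        ds = _dataset_from_fn(tiny_space, lambda s: true_ct(oracle, s), 500, 4)
        surrogate = train_and_select(ds, tiny_space, default_registry(), seed=0)
        report = weighting_factors(surrogate, tiny_space, probe_n=2000, seed=0)
        assert report.weights["a"] == pytest.approx(0.8, abs=0.05)
        assert report.weights["b"] == pytest.approx(0.2, abs=0.05)
        # category with zero planted variance stays near zero
        assert report.weights["c"] <= 0.05

    def test_weights_normalized_and_nonnegative(self, mixed_space, linear_dataset, fast_registry):
        surrogate = train_and_select(linear_dataset, mixed_space, fast_registry, seed=0)
        report = weighting_factors(surrogate, mixed_space, probe_n=600, seed=2)
        assert sum(report.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(w >= 0 for w in report.weights.values())

    def test_uninformative_surrogate_rejected(self, mixed_space):
        flatish = _dataset_from_fn(
            mixed_space, lambda s: 26.0 + 1e-12 * s.assignments["B"], 30, 5
        )
        registry = ModelRegistry({"baseline": lambda seed: DummyRegressor(strategy="mean")})
        surrogate = train_and_select(flatish, mixed_space, registry, seed=0)
        with pytest.raises(ValueError, match="uninformative"):
            weighting_factors(surrogate, mixed_space, probe_n=500, seed=0)

    def test_probe_size_minimum(self, mixed_space, linear_dataset, fast_registry):
        surrogate = train_and_select(linear_dataset, mixed_space, fast_registry, seed=0)
        with pytest.raises(ValueError):
            weighting_factors(surrogate, mixed_space, probe_n=100, seed=0)


def test_weighting_report_validates_normalization():
    with pytest.raises(ValueError):
        WeightingReport(weights={"a": 0.7, "b": 0.7})
    with pytest.raises(ValueError):
        WeightingReport(weights={"a": -0.5, "b": 1.5})
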