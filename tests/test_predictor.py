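"""Metrics, cross-validation, tuning and prediction on log10 K_m."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlago.features import encode_table
from mlago.km_dataset import KmRecord, KmTable, deduplicate, split_train_test
from mlago.predictor import (
    KM_LOWER_MM,
    KM_UPPER_MM,
    PredictorConfig,
    cross_validate,
    fit,
    load_predictor,
    predict_km,
    r_squared,
    rmse,
    save_predictor,
    tune_hyperparameters,
)
from mlago.synthetic import SyntheticKmSpec, make_synthetic_km_table

finite_vec = st.lists(st.floats(min_value=-5, max_value=5), min_size=1, max_size=10)


class TestRmse:
    @pytest.mark.parametrize(
        "q, q_ref, expected",
        [
            ([0.0, 1.0], [1.0, 1.0], 0.7071067811865476),  # sqrt(1/2)
            ([-1.0, 2.0, 0.0], [0.0, 0.0, 0.0], 1.2909944487358056),  # sqrt(5/3)
        ],
    )
    def test_hand_cases(self, q, q_ref, expected):
        assert rmse(q, q_ref) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(finite_vec)
    def test_identity_and_symmetry(self, v):
        v = np.asarray(v)
        assert rmse(v, v) == 0.0
        w = v + 0.5
        assert rmse(v, w) == pytest.approx(rmse(w, v))

    def test_zero_iff_equal(self):
        assert rmse([1.0, 2.0], [1.0, 2.0 + 1e-9]) > 0

    def test_errors(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([], [])
        with pytest.raises(ValueError):
            rmse([np.nan], [0.0])


class TestRSquared:
    def test_hand_case(self):
        assert r_squared([0.0, 1.0], [0.0, 2.0]) == pytest.approx(0.5, abs=1e-9)

    def test_perfect_prediction_is_one(self):
        v = np.array([0.3, -1.2, 2.0])
        assert r_squared(v, v) == pytest.approx(1.0)

    def test_mean_predictor_is_zero(self):
        ref = np.array([0.0, 1.0, 2.0])
        q = np.full(3, ref.mean())
        assert r_squared(q, ref) == pytest.approx(0.0)

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            q, ref = rng.normal(size=6), rng.normal(size=6)
            assert r_squared(q, ref) <= 1.0

    def test_constant_reference_raises(self):
        with pytest.raises(ValueError):
            r_squared([0.0, 1.0], [2.0, 2.0])


@pytest.fixture(scope="module")
def synthetic_table():
    table, _ = make_synthetic_km_table(SyntheticKmSpec(n_entries=600, seed=2))
    return deduplicate(table)


class TestFitPredict:
    def test_beats_mean_baseline_on_training_data(self, synthetic_table):
        pred = fit(PredictorConfig("random_forest", {"n_estimators": 50}, seed=0), synthetic_table)
        X, y = encode_table(pred.scheme, synthetic_table)
        baseline = rmse(np.full_like(y, y.mean()), y)
        assert rmse(pred.model.predict(X), y) < baseline

    def test_deterministic_given_seed(self, synthetic_table):
        cfg = PredictorConfig("random_forest", {"n_estimators": 30}, seed=5)
        queries = [r.triple for r in synthetic_table.records[:10]]
        p1 = predict_km(fit(cfg, synthetic_table), queries)
        p2 = predict_km(fit(cfg, synthetic_table), queries)
        np.testing.assert_array_equal(p1, p2)

    def test_single_record_fit_predicts_that_value(self):
        t = KmTable([KmRecord("1.1.1.1", "C00001", "T00001", 0.25)])
        pred = fit(PredictorConfig("random_forest", {"n_estimators": 10}, seed=0), t)
        out = predict_km(pred, [("9.9.9.9", "CX", "TX"), ("1.1.1.1", "C00001", "T00001")])
        np.testing.assert_allclose(out, 0.25, rtol=1e-9)

    def test_predictions_positive_and_clipped(self, synthetic_table):
        pred = fit(PredictorConfig("nearest_neighbors", {"n_neighbors": 3}, seed=0), synthetic_table)
        out = predict_km(pred, [("9.9.9.9", "CX", "TX")] + [r.triple for r in synthetic_table.records[:5]])
        assert (out > 0).all()
        assert (out >= KM_LOWER_MM).all() and (out <= KM_UPPER_MM).all()

    @pytest.mark.parametrize("algorithm", ["nearest_neighbors", "elastic_net", "random_forest", "gradient_boosting"])
    def test_all_algorithms_fit_and_predict(self, synthetic_table, algorithm):
        pred = fit(PredictorConfig(algorithm, {}, seed=0), synthetic_table)
        out = predict_km(pred, [synthetic_table[0].triple])
        assert out.shape == (1,) and np.isfinite(out).all()

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            PredictorConfig("deep_tabular", {})

    def test_persistence_round_trip(self, synthetic_table, tmp_path):
        pred = fit(PredictorConfig("random_forest", {"n_estimators": 20}, seed=1), synthetic_table)
        save_predictor(pred, tmp_path)
        loaded = load_predictor(tmp_path)
        queries = [r.triple for r in synthetic_table.records[:8]]
        np.testing.assert_array_equal(predict_km(pred, queries), predict_km(loaded, queries))


class TestCrossValidate:
    def test_constant_target_gives_zero_rmse(self):
        t = KmTable([KmRecord("1.1.1.1", f"C{i:05d}", "T00001", 1.0) for i in range(20)])
        cv = cross_validate(PredictorConfig("random_forest", {"n_estimators": 10}, 0), t,
                            k=4, rounds=1, seed=0)
        assert max(cv.per_fold_rmse) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic(self, synthetic_table):
        cfg = PredictorConfig("nearest_neighbors", {"n_neighbors": 5}, 0)
        cv1 = cross_validate(cfg, synthetic_table, k=3, rounds=2, seed=9)
        cv2 = cross_validate(cfg, synthetic_table, k=3, rounds=2, seed=9)
        assert cv1.per_fold_rmse == cv2.per_fold_rmse

    def test_positive_r2_with_signal(self, synthetic_table):
        cfg = PredictorConfig("random_forest", {"n_estimators": 50}, 0)
        cv = cross_validate(cfg, synthetic_table, k=3, rounds=1, seed=0)
        assert cv.mean_r2 > 0
        assert len(cv.per_fold_rmse) == 3

    def test_fold_count(self, synthetic_table):
        cv = cross_validate(PredictorConfig("nearest_neighbors", {}, 0), synthetic_table,
                            k=3, rounds=2, seed=0)
        assert len(cv.per_fold_rmse) == len(cv.per_fold_r2) == 6

    def test_too_few_records_raises(self):
        t = KmTable([KmRecord("1.1.1.1", "C00001", "T00001", 1.0)])
        with pytest.raises(ValueError):
            cross_validate(PredictorConfig("nearest_neighbors", {}, 0), t, k=5)

    def test_no_leakage_of_heldout_categories(self, synthetic_table):
        """A category present only in a held-out fold must encode as a zero block.

        Guarded structurally: the scheme is rebuilt per training fold, so a
        predictor fit on a training fold cannot know held-out-only codes.
        """
        df = synthetic_table.df
        train = KmTable(df.iloc[: len(df) // 2])
        held = KmTable(df.iloc[len(df) // 2 :])
        pred = fit(PredictorConfig("nearest_neighbors", {}, 0), train)
        train_codes = set(train.df["ec_number"])
        only_held = [r for r in held if r.ec_number not in train_codes]
        if only_held:
            from mlago.features import encode_record

            x = encode_record(pred.scheme, only_held[0])
            ec4 = pred.scheme.block_slices()["ec1234"]
            assert x[ec4].sum() == 0


class TestTuning:
    def test_single_point_grid(self, synthetic_table):
        cfg, scores = tune_hyperparameters(
            "nearest_neighbors", {"n_neighbors": [4]}, synthetic_table, k=3, rounds=1, seed=0
        )
        assert cfg.hyperparameters == {"n_neighbors": 4}
        assert len(scores) == 1

    def test_dominating_point_wins(self, synthetic_table):
        # k=1 memorizes noise; a moderate k dominates it on held-out folds
        cfg, scores = tune_hyperparameters(
            "nearest_neighbors", {"n_neighbors": [1, 10]}, synthetic_table, k=3, rounds=1, seed=0
        )
        assert cfg.hyperparameters["n_neighbors"] == 10
        assert scores["mean_cv_rmse"].idxmin() == 1

    def test_tie_broken_by_grid_order(self, synthetic_table):
        cfg, _ = tune_hyperparameters(
            "nearest_neighbors", {"n_neighbors": [7, 7]}, synthetic_table, k=3, rounds=1, seed=0
        )
        assert cfg.hyperparameters["n_neighbors"] == 7

    def test_empty_grid_raises(self, synthetic_table):
        with pytest.raises(ValueError):
            tune_hyperparameters("nearest_neighbors", {"n_neighbors": []}, synthetic_table)
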