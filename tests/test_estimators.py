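"""Estimators: normalization, feature ranking/selection, surrogate training."""

import numpy as np
import pandas as pd
import pytest

from ghctl import estimators as est
from ghctl.oracle import OracleParams, make_dataset


class TestNormalizer:
    def test_midpoint_maps_to_half(self):
        table = pd.DataFrame({"a": [0.0, 10.0, 5.0]})
        spec = est.fit_normalizer(table)
        assert spec.normalize(table)["a"].iloc[2] == pytest.approx(0.5)

    def test_round_trip_identity(self, rng):
        table = pd.DataFrame(rng.normal(size=(50, 4)),
                             columns=list("abcd"))
        spec = est.fit_normalizer(table)
        back = spec.denormalize(spec.normalize(table))
        np.testing.assert_allclose(back.to_numpy(), table.to_numpy(),
                                   atol=1e-9)

    def test_constant_column_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
        with pytest.raises(est.DegenerateFeatureError, match="b"):
            est.fit_normalizer(table)

    def test_clamping_bounds_unseen_values(self):
        spec = est.fit_normalizer(pd.DataFrame({"a": [0.0, 1.0]}),
                                  clamp=True)
        out = spec.normalize(pd.DataFrame({"a": [-5.0, 5.0]}))
        assert out["a"].tolist() == [0.0, 1.0]


class TestFeatureRanking:
    def test_known_driver_ranked_first(self, rng):
        n = 400
        table = pd.DataFrame({
            "featureA": rng.uniform(size=n),
            "noise1": rng.uniform(size=n),
            "noise2": rng.uniform(size=n),
            "noise3": rng.uniform(size=n),
        })
        table["target"] = 3.0 * table["featureA"] + rng.normal(0, 0.05, n)
        ranking = est.rank_features(table, ["target"], n_trees=50, seed=0)
        assert ranking.features[0] == "featureA"

    def test_importances_sum_to_one_and_descend(self, rng):
        table = pd.DataFrame(rng.uniform(size=(120, 5)),
                             columns=list("abcde"))
        table["y"] = table["a"] + 0.5 * table["b"]
        ranking = est.rank_features(table, ["y"], n_trees=30, seed=1)
        assert ranking.importances.sum() == pytest.approx(1.0)
        assert (np.diff(ranking.importances) <= 1e-12).all()

    def test_deterministic_for_fixed_seed(self, rng):
        table = pd.DataFrame(rng.uniform(size=(100, 4)),
                             columns=list("abcd"))
        table["y"] = table["a"]
        r1 = est.rank_features(table, ["y"], n_trees=20, seed=3)
        r2 = est.rank_features(table, ["y"], n_trees=20, seed=3)
        assert r1.features == r2.features
        np.testing.assert_array_equal(r1.importances, r2.importances)

    def test_missing_target_rejected(self, rng):
        table = pd.DataFrame(rng.uniform(size=(60, 3)), columns=list("abc"))
        with pytest.raises(est.FeatureSchemaError, match="zz"):
            est.rank_features(table, ["zz"])

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame({"a": range(10), "y": range(10)})
        with pytest.raises(ValueError, match="50 rows"):
            est.rank_features(table, ["y"])


@pytest.fixture(scope="module")
def ranking():
    return est.FeatureRanking([f"f{i}" for i in range(10)],
                              np.linspace(10, 1, 10))


class TestTopFeatureSelection:
    def test_top_k(self, ranking):
        assert est.select_top_features(ranking, k=3) == ["f0", "f1", "f2"]

    def test_k_equals_length_returns_all(self, ranking):
        assert est.select_top_features(ranking, k=10) == ranking.features

    def test_threshold_one_returns_all(self, ranking):
        assert est.select_top_features(
            ranking, threshold=1.0) == ranking.features

    def test_invalid_k_rejected(self, ranking):
        with pytest.raises(ValueError, match="positive"):
            est.select_top_features(ranking, k=0)
        with pytest.raises(ValueError, match="exceeds"):
            est.select_top_features(ranking, k=11)

    def test_known_crop_drivers_selected(self):
        """On oracle data the crop response is driven by temperature, light
        and irrigation; those columns must make the top of the ranking."""
        ds = make_dataset(weeks=60, seed=5)
        daily, crop = est.build_crop_sequences(ds)
        weekly = daily.groupby(np.arange(len(daily)) // 7).mean()
        table = pd.concat([
            weekly[["Tair", "Tot_PAR", "CO2air", "Cum_irr", "pH_drain_PC",
                    "EC_drain_PC", "BlackScr"]].reset_index(drop=True),
            crop.reset_index(drop=True)], axis=1)
        ranking = est.rank_features(table, list(crop.columns), n_trees=100,
                                    seed=0)
        top5 = est.select_top_features(ranking, k=5)
        assert {"Tair", "Tot_PAR", "Cum_irr"} <= set(top5)


@pytest.fixture(scope="module")
def training_dataset():
    """A 12-week low-noise dataset shared by the quick training tests."""
    return make_dataset(weeks=12, seed=21)


class TestClimateEstimator:
    def test_quick_training_recovers_dynamics(self, training_dataset):
        table = est.build_climate_table(training_dataset)
        spec = est.ClimateEstimatorSpec(hidden=(64, 64), epochs=15, seed=0)
        model, mae = est.train_climate_estimator(table, spec)
        assert mae < 0.08  # desk-scale sanity; acceptance uses full size
        pred = model.predict_normalized(table[spec.features].iloc[:16])
        assert ((pred.to_numpy() >= 0) & (pred.to_numpy() <= 1)).all()

    def test_predictions_bind_by_column_name(self, training_dataset):
        table = est.build_climate_table(training_dataset)
        spec = est.ClimateEstimatorSpec(hidden=(16, 16), epochs=2, seed=0)
        model, _ = est.train_climate_estimator(table, spec)
        rows = table[spec.features].iloc[:8]
        shuffled = rows[list(reversed(rows.columns))]
        pd.testing.assert_frame_equal(model.predict(rows),
                                      model.predict(shuffled))

    def test_feature_spec_mismatch_raises(self, training_dataset):
        table = est.build_climate_table(training_dataset).drop(
            columns=["Tout"])
        with pytest.raises(est.FeatureSchemaError, match="Tout"):
            est.train_climate_estimator(table, est.ClimateEstimatorSpec())

    def test_save_load_round_trip(self, training_dataset, tmp_path):
        table = est.build_climate_table(training_dataset)
        spec = est.ClimateEstimatorSpec(hidden=(8, 8), epochs=1, seed=0)
        model, _ = est.train_climate_estimator(table, spec)
        est.save_estimator(model, tmp_path / "climate")
        loaded = est.load_estimator(tmp_path / "climate")
        rows = table[spec.features].iloc[:5]
        pd.testing.assert_frame_equal(loaded.predict(rows),
                                      model.predict(rows))


class TestSequenceEstimator:
    def test_resource_estimator_quick_training(self, training_dataset):
        hourly, targets = est.build_resource_sequences(training_dataset)
        spec = est.SequenceEstimatorSpec(
            features=list(est.RESOURCE_SEQ_FEATURES),
            targets=list(est.RESOURCE_COLUMNS), window=24,
            conv_channels=8, hidden=16, epochs=25, seed=0)
        model, mae = est.train_sequence_estimator(hourly, targets, spec)
        assert mae < 0.12
        day = hourly.iloc[:24]
        pred = model.predict(day)
        assert set(pred.index) == set(est.RESOURCE_COLUMNS)

    def test_constant_input_gives_stable_prediction(self, training_dataset):
        hourly, targets = est.build_resource_sequences(training_dataset)
        spec = est.SequenceEstimatorSpec(
            features=list(est.RESOURCE_SEQ_FEATURES),
            targets=list(est.RESOURCE_COLUMNS), window=24,
            conv_channels=4, hidden=8, epochs=2, seed=0)
        model, _ = est.train_sequence_estimator(hourly, targets, spec)
        mid = hourly.iloc[:24].copy()
        mid[:] = hourly.iloc[:24].mean().to_numpy()
        a = model.predict_normalized(mid)
        b = model.predict_normalized(mid)
        np.testing.assert_array_equal(a, b)

    def test_window_longer_than_history_rejected(self, training_dataset):
        hourly, targets = est.build_resource_sequences(training_dataset)
        spec = est.SequenceEstimatorSpec(
            features=list(est.RESOURCE_SEQ_FEATURES),
            targets=list(est.RESOURCE_COLUMNS), window=10 ** 6)
        with pytest.raises(ValueError, match="shorter"):
            est.train_sequence_estimator(hourly, targets, spec)

    def test_feature_selected_model_is_smaller(self, training_dataset):
        daily, crop = est.build_crop_sequences(training_dataset)
        full = est.SequenceEstimatorSpec(
            features=list(est.CROP_SEQ_FEATURES), targets=est.CROP_TARGETS,
            window=7, epochs=1, seed=0)
        selected = est.SequenceEstimatorSpec(
            features=list(est.CROP_SEQ_FEATURES)[:5],
            targets=est.CROP_TARGETS, window=7, epochs=1, seed=0)
        m_full, _ = est.train_sequence_estimator(daily, crop, full)
        m_sel, _ = est.train_sequence_estimator(daily, crop, selected)
        assert m_sel.n_parameters < m_full.n_parameters
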