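"""Data split, random-forest / network training, prediction, importance."""

import numpy as np
import pandas as pd
import pytest

from ethoaccel.io_core import ParameterError
from ethoaccel.model import (
    DegenerateLabelError,
    SchemaError,
    SplitSpec,
    StateError,
    StratificationError,
    load_model,
    predict,
    save_model,
    split_data,
    train_ann,
    train_rf,
    variable_importance,
)


def synthetic_features(n_per_class, class_specs, seed=0, n_noise=3):
    """Gaussian feature table: class_specs maps label -> dict of
    feature -> (mean, sd); unlisted features are pure noise."""
    rng = np.random.default_rng(seed)
    frames = []
    feat_names = sorted({f for spec in class_specs.values() for f in spec})
    for label, spec in class_specs.items():
        data = {}
        for f in feat_names:
            mu, sd = spec.get(f, (0.0, 1.0))
            data[f] = rng.normal(mu, sd, n_per_class)
        for k in range(n_noise):
            data[f"noise_{k}"] = rng.normal(0, 1, n_per_class)
        data["majority_label"] = label
        data["animal_id"] = "a01"
        data["start_time"] = np.arange(n_per_class)
        data["label_purity"] = 1.0
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


TWO_CLASS = {
    "Foraging": {"iqr_x": (10.0, 1.0), "sd_x": (8.0, 1.0)},
    "RSP": {"iqr_x": (1.0, 0.5), "sd_x": (0.8, 0.3)},
}


class TestSplitData:
    def test_fraction_arithmetic(self):
        table = synthetic_features(500, TWO_CLASS)
        train, val, test = split_data(table, SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (500, 250, 250)
        assert len(train) + len(val) + len(test) == len(table)

    def test_subsets_are_disjoint_and_exhaustive(self):
        table = synthetic_features(100, TWO_CLASS)
        table["row_id"] = np.arange(len(table))
        train, val, test = split_data(table, SplitSpec(seed=3))
        ids = np.concatenate([t["row_id"].to_numpy() for t in (train, val, test)])
        assert sorted(ids) == list(range(len(table)))

    def test_rare_class_reaches_every_subset(self):
        table = synthetic_features(60, TWO_CLASS, seed=1)
        rare = synthetic_features(
            3, {"Walking": {"iqr_x": (5.0, 1.0), "sd_x": (4.0, 1.0)}}, seed=2
        )
        table = pd.concat([table, rare[table.columns]], ignore_index=True)
        for seed in range(5):
            for sub in split_data(table, SplitSpec(seed=seed)):
                assert "Walking" in set(sub["majority_label"])

    def test_class_below_three_windows_rejected(self):
        table = synthetic_features(50, TWO_CLASS)
        tiny = synthetic_features(
            2, {"Walking": {"iqr_x": (5.0, 1.0), "sd_x": (4.0, 1.0)}}, seed=2
        )
        table = pd.concat([table, tiny[table.columns]], ignore_index=True)
        with pytest.raises(StratificationError, match="Walking"):
            split_data(table, SplitSpec(seed=0))

    def test_same_seed_gives_identical_assignment(self):
        table = synthetic_features(80, TWO_CLASS)
        a = split_data(table, SplitSpec(seed=11))
        b = split_data(table, SplitSpec(seed=11))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            SplitSpec(train=0.5, validation=0.3, test=0.3)


class TestTrainRf:
    def test_separable_classes_reach_high_validation_accuracy(self):
        table = synthetic_features(200, TWO_CLASS, seed=7)
        train, val, test = split_data(table, SplitSpec(seed=7))
        model = train_rf(train, val, seed=7)
        assert model.metadata["validation_mean_balanced_accuracy_pct"] >= 95.0

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(0)
        accs = []
        for rep in range(10):
            table = synthetic_features(120, TWO_CLASS, seed=rep)
            table["majority_label"] = rng.permutation(table["majority_label"].to_numpy())
            train, val, test = split_data(table, SplitSpec(seed=rep))
            model = train_rf(train, val, n_trees=50, seed=rep)
            labels, _ = predict(model, test)
            actual = test["majority_label"].to_numpy()
            sens = [
                np.mean(labels[actual == c] == c) for c in model.classes
            ]
            accs.append(np.mean(sens))
        # balanced accuracy of a label-free predictor is 0.5 on average
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_zero_trees_rejected(self):
        table = synthetic_features(50, TWO_CLASS)
        train, val, _ = split_data(table, SplitSpec(seed=0))
        with pytest.raises(ParameterError):
            train_rf(train, val, n_trees=0)

    def test_single_class_training_rejected(self):
        table = synthetic_features(50, {"Foraging": {"iqr_x": (10.0, 1.0)}})
        with pytest.raises(DegenerateLabelError):
            train_rf(table, table)

    def test_train_predict_path_is_deterministic(self):
        table = synthetic_features(100, TWO_CLASS, seed=2)
        train, val, test = split_data(table, SplitSpec(seed=2))
        a = train_rf(train, val, seed=5)
        b = train_rf(train, val, seed=5)
        la, pa = predict(a, test)
        lb, pb = predict(b, test)
        np.testing.assert_array_equal(la, lb)
        pd.testing.assert_frame_equal(pa, pb)


class TestPredict:
    @pytest.fixture()
    def fitted(self):
        table = synthetic_features(100, TWO_CLASS, seed=4)
        train, val, test = split_data(table, SplitSpec(seed=4))
        return train_rf(train, val, seed=4), train, test

    def test_resubstitution_matches_logged_training_accuracy(self, fitted):
        model, train, _ = fitted
        labels, _ = predict(model, train)
        acc = 100.0 * np.mean(labels == train["majority_label"].to_numpy())
        assert acc >= model.metadata["training_accuracy_pct"] - 1e-9

    def test_probabilities_sum_to_one(self, fitted):
        model, _, test = fitted
        _, proba = predict(model, test)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_label_column_is_ignored(self, fitted):
        model, _, test = fitted
        unk = test.copy()
        unk["majority_label"] = "Unknown"
        labels, _ = predict(model, unk)
        ref, _ = predict(model, test)
        np.testing.assert_array_equal(labels, ref)

    def test_schema_mismatch_lists_columns(self, fitted):
        model, _, test = fitted
        broken = test.drop(columns=["iqr_x"]).assign(bogus=1.0)
        with pytest.raises(SchemaError, match="iqr_x"):
            predict(model, broken)

    def test_model_archive_round_trip(self, fitted, tmp_path):
        model, _, test = fitted
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        assert back.feature_columns == model.feature_columns
        assert back.metadata == model.metadata
        np.testing.assert_array_equal(predict(back, test)[0], predict(model, test)[0])


class TestVariableImportance:
    def test_informative_channel_dominates(self):
        specs = {
            "Foraging": {
                "iqr_x": (10, 1), "sd_x": (8, 1), "mean_x": (5, 1),
                "median_x": (5, 1), "var_x": (60, 8),
            },
            "RSP": {
                "iqr_x": (1, 0.5), "sd_x": (0.8, 0.3), "mean_x": (-5, 1),
                "median_x": (-5, 1), "var_x": (0.6, 0.2),
            },
        }
        table = synthetic_features(150, specs, seed=3, n_noise=5)
        train, val, _ = split_data(table, SplitSpec(seed=3))
        model = train_rf(train, val, seed=3)
        imp = variable_importance(model)
        top5 = [name for name, _ in imp[:5]]
        assert all(name.endswith("_x") for name in top5)

    def test_scaled_descending_and_non_negative(self):
        table = synthetic_features(80, TWO_CLASS, seed=6)
        train, val, _ = split_data(table, SplitSpec(seed=6))
        imp = variable_importance(train_rf(train, val, seed=6))
        values = [v for _, v in imp]
        assert values[0] == 1.0
        assert all(a >= b >= 0.0 for a, b in zip(values, values[1:]))

    def test_unfitted_model_raises_state_error(self):
        from ethoaccel.model import TrainedModel

        with pytest.raises(StateError):
            variable_importance(TrainedModel(object(), [], []))


class TestTrainAnn:
    def test_separable_classes_learned(self):
        table = synthetic_features(150, TWO_CLASS, seed=8)
        train, val, _ = split_data(table, SplitSpec(seed=8))
        model = train_ann(train, val, layers=(225, 225), seed=8, max_iter=80)
        assert model.metadata["validation_mean_balanced_accuracy_pct"] >= 90.0

    def test_deterministic_under_fixed_seed(self):
        table = synthetic_features(60, TWO_CLASS, seed=9)
        train, val, test = split_data(table, SplitSpec(seed=9))
        a = train_ann(train, val, layers=(16,), seed=1, max_iter=40)
        b = train_ann(train, val, layers=(16,), seed=1, max_iter=40)
        np.testing.assert_array_equal(predict(a, test)[0], predict(b, test)[0])

    def test_bad_layer_sizes_rejected(self):
        table = synthetic_features(50, TWO_CLASS)
        train, val, _ = split_data(table, SplitSpec(seed=0))
        with pytest.raises(ParameterError):
            train_ann(train, val, layers=(0,))
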