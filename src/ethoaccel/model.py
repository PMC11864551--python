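"""Behaviour classifiers: data split, random-forest training (default),
feed-forward network (parity option), prediction and variable importance.

The split protocol assigns whole windows at random to train / validation
/ test at 50 / 25 / 25 %, redrawing (bounded) until every behaviour class
is present in all three subsets.  The default classifier is a random
forest of 100 trees with all other hyperparameters at the library
defaults; class imbalance is deliberately left untreated (no weights) and
performance is judged with balanced accuracy instead.  Variable
importance is the forest's mean decrease in impurity scaled so the top
feature equals 1.0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import METADATA_COLUMNS
from .io_core import EthoaccelError, ParameterError

logger = logging.getLogger("ethoaccel")

__all__ = [
    "SplitSpec",
    "TrainedModel",
    "split_data",
    "train_rf",
    "train_ann",
    "predict",
    "variable_importance",
    "save_model",
    "load_model",
]

LABEL_COLUMN = "majority_label"


class StratificationError(EthoaccelError):
    """A class is too rare to appear in every data subset."""


class SchemaError(EthoaccelError):
    """Feature table schema differs from the one the model was fitted on."""


class DegenerateLabelError(EthoaccelError):
    """Training data carries fewer than two classes."""


class StateError(EthoaccelError):
    """Operation on an unfitted model."""


@dataclass(frozen=True)
class SplitSpec:
    """Random per-window split fractions (must sum to 1) plus seed."""

    train: float = 0.50
    validation: float = 0.25
    test: float = 0.25
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ParameterError("split fractions must sum to 1")


@dataclass
class TrainedModel:
    """A fitted classifier plus the feature schema it expects."""

    estimator: object
    feature_columns: list[str]
    classes: list[str]
    metadata: dict = field(default_factory=dict)


def _feature_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    feats = columns if columns is not None else [c for c in table.columns if c not in METADATA_COLUMNS]
    return table[feats].to_numpy(dtype=np.float64), list(feats)


def split_data(table: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a feature table into train / validation / test subsets.

    Subset sizes are the fractions rounded to the nearest integer (test
    takes the remainder).  If any class is missing from any subset the
    assignment is redrawn with an incremented seed, up to
    ``spec.max_retries`` times; each class therefore needs at least 3
    windows up front.
    """
    counts = table[LABEL_COLUMN].value_counts()
    too_rare = counts[counts < 3]
    if len(too_rare):
        raise StratificationError(
            f"class(es) with fewer than 3 windows cannot reach every subset: {dict(too_rare)}"
        )
    n = len(table)
    n_train = int(round(n * spec.train))
    n_val = int(round(n * spec.validation))
    classes = set(counts.index)
    for attempt in range(spec.max_retries):
        rng = np.random.default_rng(spec.seed + attempt)
        perm = rng.permutation(n)
        parts = (perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :])
        subsets = [table.iloc[p].reset_index(drop=True) for p in parts]
        if all(set(sub[LABEL_COLUMN]) == classes for sub in subsets):
            if attempt:
                logger.info("split: class coverage reached after %d redraw(s)", attempt)
            return tuple(subsets)
    raise StratificationError(
        f"could not place every class in every subset within {spec.max_retries} redraws"
    )


def _validation_summary(model: TrainedModel, validation: pd.DataFrame) -> dict:
    from . import evaluate  # local import: evaluate builds on this module

    labels, _ = predict(model, validation)
    cm = evaluate.confusion_matrix(
        validation[LABEL_COLUMN].to_numpy(), labels, model.classes
    )
    metrics = evaluate.class_metrics(cm)
    return {
        "validation_overall_accuracy_pct": metrics.overall_accuracy,
        "validation_mean_balanced_accuracy_pct": evaluate.mean_balanced_accuracy(metrics),
        "validation_balanced_accuracy_pct": {
            c: metrics.per_class.loc[c, "balanced_accuracy"] for c in model.classes
        },
    }


def _check_train_inputs(train: pd.DataFrame, validation: pd.DataFrame) -> None:
    if list(train.columns) != list(validation.columns):
        raise SchemaError("train and validation tables must share one schema")
    if train[LABEL_COLUMN].nunique() < 2:
        raise DegenerateLabelError("training set carries a single class")


def train_rf(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    n_trees: int = 100,
    seed: int = 0,
    window_s: int | None = None,
) -> TrainedModel:
    """Fit the default random-forest classifier (100 trees, library
    defaults otherwise) and log validation metrics.

    The validation subset is used for logging and model comparison only;
    random forests need no early stopping.
    """
    if n_trees <= 0:
        raise ParameterError("n_trees must be a positive integer")
    _check_train_inputs(train, validation)
    x, feats = _feature_matrix(train)
    y = train[LABEL_COLUMN].to_numpy()
    est = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    est.fit(x, y)
    model = TrainedModel(
        est,
        feats,
        [str(c) for c in est.classes_],
        {"algorithm": "random_forest", "n_trees": n_trees, "seed": seed, "window_s": window_s},
    )
    model.metadata["training_accuracy_pct"] = 100.0 * float(np.mean(est.predict(x) == y))
    model.metadata.update(_validation_summary(model, validation))
    logger.info(
        "random forest: %d trees, %d features, %d classes; validation mean balanced accuracy %.2f%%",
        n_trees, len(feats), len(model.classes),
        model.metadata["validation_mean_balanced_accuracy_pct"],
    )
    return model


def train_ann(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    layers: tuple[int, ...] = (225, 225),
    seed: int = 0,
    window_s: int | None = None,
    max_iter: int = 200,
) -> TrainedModel:
    """Feed-forward network parity option (default two hidden layers of
    225 units) behind a standard-scaler pipeline.

    Early stopping uses the fitter's internal validation split; the
    protocol's validation subset is scored afterwards for comparison with
    the forest, and no accuracy claim is attached to this variant.
    """
    if any(h <= 0 for h in layers):
        raise ParameterError("layer sizes must be positive")
    _check_train_inputs(train, validation)
    x, feats = _feature_matrix(train)
    y = train[LABEL_COLUMN].to_numpy()
    est = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=tuple(layers),
                    random_state=seed,
                    early_stopping=True,
                    max_iter=max_iter,
                ),
            ),
        ]
    )
    est.fit(x, y)
    model = TrainedModel(
        est,
        feats,
        [str(c) for c in est.named_steps["mlp"].classes_],
        {"algorithm": "ann", "layers": list(layers), "seed": seed, "window_s": window_s},
    )
    model.metadata["training_accuracy_pct"] = 100.0 * float(np.mean(est.predict(x) == y))
    model.metadata.update(_validation_summary(model, validation))
    logger.info(
        "ann %s: validation mean balanced accuracy %.2f%%",
        layers, model.metadata["validation_mean_balanced_accuracy_pct"],
    )
    return model


def predict(model: TrainedModel, table: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Predicted label plus class probabilities per window.

    The table's feature columns must match the stored schema exactly; any
    label column present (for example all-``Unknown`` placeholders) is
    ignored.
    """
    have = [c for c in table.columns if c not in METADATA_COLUMNS]
    missing = [c for c in model.feature_columns if c not in have]
    extra = [c for c in have if c not in model.feature_columns]
    if missing or extra:
        raise SchemaError(f"feature schema mismatch; missing={missing[:5]} extra={extra[:5]}")
    x, _ = _feature_matrix(table, model.feature_columns)
    proba = model.estimator.predict_proba(x)
    labels = np.asarray(model.estimator.predict(x), dtype=object)
    return labels, pd.DataFrame(proba, columns=model.classes)


def variable_importance(model: TrainedModel) -> list[tuple[str, float]]:
    """(feature, relative importance) pairs, descending, scaled so the
    top feature is exactly 1.0 (mean decrease in impurity)."""
    est = model.estimator
    if not hasattr(est, "feature_importances_"):
        raise StateError("variable importance requires a fitted random forest")
    imp = np.asarray(est.feature_importances_, dtype=np.float64)
    top = imp.max()
    if top > 0:
        imp = imp / top
    order = np.argsort(-imp, kind="mergesort")
    return [(model.feature_columns[i], float(imp[i])) for i in order]


def save_model(model: TrainedModel, path) -> None:
    """Persist estimator + schema + metadata as one archive."""
    joblib.dump(
        {
            "estimator": model.estimator,
            "feature_columns": model.feature_columns,
            "classes": model.classes,
            "metadata_json": json.dumps(model.metadata),
        },
        path,
    )


def load_model(path) -> TrainedModel:
    blob = joblib.load(path)
    return TrainedModel(
        blob["estimator"],
        list(blob["feature_columns"]),
        list(blob["classes"]),
        json.loads(blob["metadata_json"]),
    )
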