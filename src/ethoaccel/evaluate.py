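"""Confusion matrix, per-class metrics, observer agreement and the
window-size sweep experiment.

Per-class metrics follow the one-vs-rest convention: sensitivity is the
true-positive rate of a class, specificity its true-negative rate, and
balanced accuracy their mean — the appropriate headline number under the
strong class imbalance typical of behaviour data, where overall accuracy
mostly reflects the dominant class.  A class that is never predicted and
never correct has sensitivity 0, specificity 100 and balanced accuracy
exactly 50.  Percentages are computed from exact cell counts and rounded
half-away-from-zero only at presentation.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import build_feature_table
from .io_core import EthoaccelError, LabelledSeries, ParameterError
from .windows import make_windows

logger = logging.getLogger("ethoaccel")

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion_matrix",
    "class_metrics",
    "mean_balanced_accuracy",
    "cohen_kappa",
    "clopper_pearson",
    "rank_correlation",
    "window_size_sweep",
    "run_single_size",
    "round_half_away",
    "WILD_BOAR_REFERENCE_CONFUSION",
]

#: Reference confusion matrix (actual rows x predicted columns) of the
#: best 30-s-window random-forest model for the seven-behaviour wild-boar
#: ethogram classified from 1 Hz ear-tag acceleration.  Used by the
#: worked example and the metric-reconstruction checks: it exercises the
#: full metric path including never-predicted classes.
WILD_BOAR_REFERENCE_CONFUSION: dict = {
    "classes": ("RLP", "RSP", "Foraging", "Lactating", "Scrubbing", "Standing", "Walking"),
    "counts": (
        (33, 0, 1, 0, 0, 1, 0),
        (1, 62, 5, 1, 0, 3, 0),
        (0, 0, 1013, 0, 0, 4, 0),
        (1, 2, 1, 13, 0, 0, 0),
        (0, 0, 2, 0, 0, 0, 0),
        (1, 2, 12, 0, 0, 17, 0),
        (0, 0, 25, 0, 0, 0, 0),
    ),
}


class InputError(EthoaccelError):
    """Inconsistent evaluation inputs."""


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (presentation convention; Python's
    built-in round is banker's rounding)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Actual-class (rows) x predicted-class (columns) count table."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if k == 0:
            raise InputError("empty class list")
        if counts.shape != (k, k):
            raise InputError(f"counts must be {k}x{k}, got {counts.shape}")
        if np.any(counts < 0):
            raise InputError("negative cell count")
        object.__setattr__(self, "counts", counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self, totals: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))
        if totals:
            df["Total"] = self.row_totals
            df.loc["Total"] = list(self.col_totals) + [self.grand_total]
        return df


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class sensitivity/specificity/balanced accuracy (percent) and
    overall summary; per-class values are NaN where undefined (a class
    with no actual occurrences)."""

    per_class: pd.DataFrame
    overall_accuracy: float
    total_error: float
    accuracy_ci: tuple[float, float]


def confusion_matrix(
    actual: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Count table over a fixed class list; classes with zero support are
    retained as zero rows."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise InputError(f"label sequences differ in length ({len(actual)} vs {len(predicted)})")
    classes = tuple(str(c) for c in classes)
    if not classes:
        raise InputError("empty class list")
    index = {c: i for i, c in enumerate(classes)}
    bad = sorted({str(v) for v in actual + predicted} - set(classes))
    if bad:
        raise InputError(f"labels outside the class list: {bad}")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        counts[index[str(a)], index[str(p)]] += 1
    return ConfusionMatrix(classes, counts)


def clopper_pearson(successes: int, total: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if total <= 0:
        raise ParameterError("total must be positive")
    k, n = successes, total
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Sensitivity, specificity, balanced accuracy, error rate and support
    per class (percent), plus overall accuracy with an exact binomial CI.

    For class i with diagonal d_i, row total r_i and column total c_i out
    of N windows: sensitivity = 100 d_i / r_i, specificity =
    100 (1 - (c_i - d_i) / (N - r_i)), balanced accuracy their mean.  A
    class with r_i = 0 has undefined sensitivity; it is reported as NaN
    and excluded from the mean balanced accuracy with a warning.
    """
    total = cm.grand_total
    if total <= 0:
        raise InputError("empty confusion matrix")
    diag = np.diag(cm.counts).astype(np.float64)
    rows = cm.row_totals.astype(np.float64)
    cols = cm.col_totals.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = 100.0 * diag / rows
        spec = 100.0 * (1.0 - (cols - diag) / (total - rows))
    undefined = rows == 0
    if undefined.any():
        warnings.warn(
            f"class(es) with zero actual occurrences: "
            f"{[c for c, u in zip(cm.classes, undefined) if u]}; sensitivity undefined",
            stacklevel=2,
        )
        sens[undefined] = np.nan
    ba = (sens + spec) / 2.0
    per_class = pd.DataFrame(
        {
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": ba,
            "error_rate": 1.0 - sens / 100.0,
            "support": cm.row_totals,
        },
        index=list(cm.classes),
    )
    trace = int(np.trace(cm.counts))
    ci = clopper_pearson(trace, total)
    return ClassMetrics(
        per_class=per_class,
        overall_accuracy=100.0 * trace / total,
        total_error=1.0 - trace / total,
        accuracy_ci=(100.0 * ci[0], 100.0 * ci[1]),
    )


def mean_balanced_accuracy(metrics: ClassMetrics) -> float:
    """Unweighted mean of the per-class balanced accuracies (percent),
    skipping classes whose metrics are undefined."""
    ba = metrics.per_class["balanced_accuracy"].to_numpy(dtype=np.float64)
    defined = ~np.isnan(ba)
    if not defined.any():
        raise InputError("no class has defined metrics")
    return float(ba[defined].mean())


def cohen_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Unweighted Cohen's kappa between two raters: (p_o - p_e)/(1 - p_e)
    with observed agreement p_o and chance agreement p_e from the two
    marginal label distributions.  Defined as 1 when both raters agree
    perfectly on a constant sequence (p_e = 1)."""
    a = np.asarray(list(labels_a), dtype=object)
    b = np.asarray(list(labels_b), dtype=object)
    if len(a) != len(b):
        raise InputError("label sequences differ in length")
    if len(a) == 0:
        raise InputError("empty label sequences")
    n = len(a)
    vocab = sorted({str(v) for v in a} | {str(v) for v in b})
    pa = np.array([np.mean(a == v) for v in vocab])
    pb = np.array([np.mean(b == v) for v in vocab])
    p_o = float(np.mean(a == b))
    p_e = float(pa @ pb)
    if abs(1.0 - p_e) < 1e-15:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (generic utility, e.g. for relating a
    class's sensitivity to how common it is)."""
    return float(sps.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# Window-size sweep
# ---------------------------------------------------------------------------


def _block_subset(seed: int, animal_id: str, block: int, fractions=(0.5, 0.25, 0.25)) -> int:
    """Deterministic subset (0 train, 1 validation, 2 test) for one time
    block of one animal, independent of traversal order and window size."""
    digest = hashlib.blake2b(
        f"{seed}|{animal_id}|{block}".encode(), digest_size=8
    ).digest()
    u = int.from_bytes(digest, "big") / 2**64
    if u < fractions[0]:
        return 0
    if u < fractions[0] + fractions[1]:
        return 1
    return 2


def run_single_size(
    series: LabelledSeries | list[LabelledSeries],
    window_s: int,
    seed: int = 0,
    overlap: float = 0.5,
    n_trees: int = 100,
    block_s: int | None = None,
    min_train_windows_per_class: int = 10,
) -> dict:
    """One featurize -> block-split -> train -> evaluate pass at a single
    window size, with the time-blocked partition used by the sweep.

    The partition assigns fixed-length time blocks (default 120 s) of
    each animal's timeline to train / validation / test, so the same
    seconds are test seconds at every window size — the prerequisite for
    comparing sizes on identical test data.  Classes with fewer than
    ``min_train_windows_per_class`` training windows at this size are
    dropped from the model and the metrics, with a warning.
    """
    from . import model as model_mod

    if block_s is None:
        block_s = 120
    ws = make_windows(series, window_s, overlap)
    table = build_feature_table(ws)
    n_windows = len(table)
    subset = np.array(
        [
            _block_subset(seed, a, int(t) // block_s)
            for a, t in zip(table["animal_id"], table["start_time"])
        ]
    )
    train = table[subset == 0]
    val = table[subset == 1]
    test = table[subset == 2]

    counts = train["majority_label"].value_counts()
    kept = sorted(c for c in counts.index if counts[c] >= min_train_windows_per_class)
    dropped = sorted(set(table["majority_label"]) - set(kept))
    if dropped:
        warnings.warn(
            f"window {window_s}s: class(es) {dropped} have fewer than "
            f"{min_train_windows_per_class} training windows and are dropped at this size",
            stacklevel=2,
        )
    if len(kept) < 2:
        return {"window_s": window_s, "n_windows": n_windows, "skipped": True}

    train = train[train["majority_label"].isin(kept)].reset_index(drop=True)
    val = val[val["majority_label"].isin(kept)].reset_index(drop=True)
    test = test[test["majority_label"].isin(kept)].reset_index(drop=True)
    if val["majority_label"].nunique() < 1 or len(test) == 0:
        return {"window_s": window_s, "n_windows": n_windows, "skipped": True}

    fitted = model_mod.train_rf(train, val, n_trees=n_trees, seed=seed, window_s=window_s)
    pred, _ = model_mod.predict(fitted, test)
    cm = confusion_matrix(test["majority_label"].to_numpy(), pred, kept)
    metrics = class_metrics(cm)
    ba = metrics.per_class["balanced_accuracy"].to_numpy(dtype=np.float64)
    ba = ba[~np.isnan(ba)]
    return {
        "window_s": window_s,
        "n_windows": n_windows,
        "skipped": False,
        "classes": kept,
        "mean_balanced_accuracy": float(np.mean(ba)),
        "sd_balanced_accuracy": float(np.std(ba, ddof=1)) if len(ba) > 1 else 0.0,
        "overall_accuracy": metrics.overall_accuracy,
        "confusion": cm,
    }


def window_size_sweep(
    series: LabelledSeries | list[LabelledSeries],
    sizes: Sequence[int] = (6, 10, 20, 30, 40, 50, 60),
    seed: int = 0,
    overlap: float = 0.5,
    n_trees: int = 100,
    block_s: int | None = None,
    min_train_windows_per_class: int = 10,
) -> pd.DataFrame:
    """Mean balanced accuracy (± SD across classes) and window count per
    window size, on identical test seconds at every size.

    Returns one row per size with columns ``window_s, n_windows,
    mean_balanced_accuracy, sd_balanced_accuracy, overall_accuracy,
    n_classes, skipped``.  The trade-off this experiment exposes is the
    core sizing decision of low-rate behaviour classification: longer
    windows stabilise the window statistics but shrink the data base
    (window count) and mix more behaviours per window.
    """
    if block_s is None:
        block_s = 120  # 2x the largest standard size, fixed so the
        # partition is identical whatever subset of sizes is swept
    rows = []
    for size in sizes:
        res = run_single_size(
            series, int(size), seed=seed, overlap=overlap, n_trees=n_trees,
            block_s=block_s, min_train_windows_per_class=min_train_windows_per_class,
        )
        rows.append(
            {
                "window_s": res["window_s"],
                "n_windows": res["n_windows"],
                "mean_balanced_accuracy": res.get("mean_balanced_accuracy", np.nan),
                "sd_balanced_accuracy": res.get("sd_balanced_accuracy", np.nan),
                "overall_accuracy": res.get("overall_accuracy", np.nan),
                "n_classes": len(res.get("classes", [])),
                "skipped": res["skipped"],
            }
        )
        logger.info(
            "sweep size %ds: %d windows, mean balanced accuracy %.2f",
            size, rows[-1]["n_windows"], rows[-1]["mean_balanced_accuracy"],
        )
    return pd.DataFrame(rows)
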