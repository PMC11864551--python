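"""Window → feature-vector conversion: 11 summary statistics per channel
plus periodogram power at every nonzero Fourier frequency.

The statistic set covers location (mean, median), dispersion (standard
deviation, variance, range, interquartile range, root-mean-square) and
shape (skewness, kurtosis) together with the extremes — eleven numbers
per channel.  Kurtosis is the raw (non-excess) fourth standardised
moment; skewness and kurtosis of a zero-variance window are imputed as 0
so every feature is finite.  Spectral features are raw periodogram
ordinates of the mean-centred signal at the Fourier frequencies
k/W for k = 1..floor(W/2); nothing above the Nyquist frequency (half the
sampling rate) exists, the central constraint of low-rate accelerometry.

Feature columns are named ``<stat>_<channel>`` and
``pow<freq>_<channel>`` with channels x, y, z (raw) and xj, yj, zj
(jerk-filtered), so an importance listing immediately shows which axis
mattered and whether it was jerk-corrected.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import EthoaccelError, InsufficientDataError
from .windows import WindowSet

__all__ = [
    "STAT_NAMES",
    "window_statistics",
    "spectral_power",
    "build_feature_table",
    "feature_columns",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("animal_id", "start_time", "majority_label", "label_purity")

#: The 11 per-channel summary statistics, in stable column order.
STAT_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "sd",
    "var",
    "skew",
    "kurt",
    "min",
    "max",
    "range",
    "iqr",
    "rms",
)


class ConsistencyError(EthoaccelError):
    """Windows of mixed lengths in one feature table."""


def _stat_matrix(v: np.ndarray, quantile_method: str) -> np.ndarray:
    """(m, 11) statistics for m windows stacked as rows of ``v``."""
    v = np.atleast_2d(np.asarray(v, dtype=np.float64))
    q25, q75 = np.percentile(v, [25.0, 75.0], axis=1, method=quantile_method)
    var = np.var(v, axis=1, ddof=1)
    degenerate = var == 0
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant windows trigger a scipy precision warning; their
        # skew/kurt are imputed below so the warning is moot
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = sps.skew(v, axis=1, bias=True)
        kurt = sps.kurtosis(v, axis=1, fisher=False, bias=True)
    skew = np.where(degenerate, 0.0, skew)  # imputed for constant windows
    kurt = np.where(degenerate, 0.0, kurt)
    mn = v.min(axis=1)
    mx = v.max(axis=1)
    return np.column_stack(
        [
            v.mean(axis=1),
            np.median(v, axis=1),
            np.sqrt(var),
            var,
            skew,
            kurt,
            mn,
            mx,
            mx - mn,
            q75 - q25,
            np.sqrt(np.mean(v**2, axis=1)),
        ]
    )


def _stat_vector(v: np.ndarray, quantile_method: str) -> np.ndarray:
    return _stat_matrix(v[None, :], quantile_method)[0]


def _power_matrix(v: np.ndarray) -> np.ndarray:
    """One-sided periodogram ordinates (nonzero frequencies) for m
    windows stacked as rows; same normalisation as :func:`spectral_power`."""
    v = np.atleast_2d(np.asarray(v, dtype=np.float64))
    n = v.shape[1]
    x = np.fft.rfft(v - v.mean(axis=1, keepdims=True), axis=1)
    power = np.abs(x[:, 1:]) ** 2 / n
    scale = np.full(n // 2, 2.0)
    if n % 2 == 0:
        scale[-1] = 1.0
    return power * scale


def window_statistics(values: Sequence[float], quantile_method: str = "linear") -> dict[str, float]:
    """The 11 summary statistics of one channel of one window.

    ``sd``/``var`` use the sample (n-1) convention; ``skew``/``kurt`` the
    population convention (kurtosis non-excess); the IQR quantiles use
    linear interpolation between order statistics by default
    (``quantile_method`` is passed to :func:`numpy.percentile`).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 4:
        raise InsufficientDataError("window statistics need at least 4 values")
    return dict(zip(STAT_NAMES, _stat_vector(v, quantile_method)))


def spectral_power(values: Sequence[float], sampling_rate_hz: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Periodogram ordinates of a mean-centred window at the nonzero
    Fourier frequencies.

    Returns ``(freqs, power)`` with freqs = k·fs/n for k = 1..floor(n/2),
    all at or below the Nyquist frequency fs/2.  The one-sided
    normalisation satisfies Parseval's identity: the ordinates sum to the
    window's total centred energy, i.e. n times the population variance.
    """
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    if n < 4:
        raise InsufficientDataError("spectral power needs at least 4 values")
    k = np.arange(1, n // 2 + 1)
    # Nyquist bin (even n) is not duplicated in the two-sided sum
    return k * sampling_rate_hz / n, _power_matrix(v[None, :])[0]


def feature_columns(
    channels: Sequence[str],
    window_samples: int,
    sampling_rate_hz: float = 1.0,
    stats: Sequence[str] = STAT_NAMES,
) -> list[str]:
    """Stable feature-column order for a given channel set and window."""
    cols = [f"{stat}_{ch}" for ch in channels for stat in stats]
    k = np.arange(1, window_samples // 2 + 1)
    freqs = k * sampling_rate_hz / window_samples
    cols += [f"pow{f:.4f}_{ch}" for ch in channels for f in freqs]
    return cols


def build_feature_table(
    windows: WindowSet,
    channels: Sequence[str] | None = None,
    quantile_method: str = "linear",
    custom_stats: dict[str, Callable[[np.ndarray], float]] | None = None,
) -> pd.DataFrame:
    """One row per window: statistics + spectral power per channel, plus
    the metadata columns ``animal_id, start_time, majority_label,
    label_purity``.  Rows are sorted by (animal_id, start_time).

    ``custom_stats`` replaces the default 11-statistic set with arbitrary
    named callables for users who want their own summary set.
    """
    if len(windows) == 0:
        raise InsufficientDataError("empty window set")
    channels = tuple(channels) if channels is not None else windows.channel_names
    w = windows.samples_per_window
    for win in windows:
        if any(len(win.channels[c]) != w for c in channels):
            raise ConsistencyError("mixed window lengths in one WindowSet")

    if custom_stats is None:
        stat_names = STAT_NAMES

        def stat_fn(v: np.ndarray) -> np.ndarray:
            return _stat_matrix(v, quantile_method)

    else:
        stat_names = tuple(custom_stats)

        def stat_fn(v: np.ndarray) -> np.ndarray:
            return np.column_stack(
                [np.apply_along_axis(fn, 1, v) for fn in custom_stats.values()]
            ).astype(np.float64)

    cols = feature_columns(channels, w, windows.sampling_rate_hz, stat_names)
    stacks = {c: np.vstack([win.channels[c] for win in windows]) for c in channels}
    stat_blocks = [stat_fn(stacks[c]) for c in channels]
    pow_blocks = [_power_matrix(stacks[c]) for c in channels]
    rows = np.hstack(stat_blocks + pow_blocks)
    meta = {
        "animal_id": [win.animal_id for win in windows],
        "start_time": [win.start_time for win in windows],
        "majority_label": [win.majority_label for win in windows],
        "label_purity": [win.label_purity for win in windows],
    }

    table = pd.DataFrame(rows, columns=cols)
    for c in METADATA_COLUMNS:
        table[c] = meta[c]
    table = table.sort_values(["animal_id", "start_time"], kind="mergesort").reset_index(drop=True)
    return table


def write_feature_table(table: pd.DataFrame, path, schema_path=None) -> None:
    """Serialise a feature table as CSV with a JSON schema sidecar listing
    the feature columns in order."""
    import json
    from pathlib import Path

    table.to_csv(path, index=False)
    if schema_path is None:
        schema_path = Path(path).with_suffix(".schema.json")
    feats = [c for c in table.columns if c not in METADATA_COLUMNS]
    Path(schema_path).write_text(json.dumps({"feature_columns": feats}, indent=1))


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
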