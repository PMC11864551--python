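"""Canonical in-memory types and delimited-text I/O for acceleration streams.

The package works on per-animal triaxial acceleration sampled at a low,
constant rate (1 Hz by default, the regime of ear-tag biologgers).  Two
streams exist: the acceleration itself and, for supervised work, a
behaviour label per second drawn from a closed ethogram vocabulary.

Timestamps are integers counting sample periods (plain seconds at 1 Hz).
Sub-second timestamps in input files are truncated to the second: both
streams are coded at the accelerometer rate, and behaviours shorter than
one sample are unrepresentable by construction.  A *contiguous segment* is
a maximal run of records whose timestamps increase by exactly one period;
downstream transforms and windows never cross segment boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ethoaccel")

#: Closed ethogram vocabulary (wild-boar behaviours plus the catch-all
#: "Other").  "Unknown" is only valid in prediction mode, i.e. when the
#: labels are placeholders for behaviour still to be predicted.
BEHAVIOURS: tuple[str, ...] = (
    "RLP",
    "RSP",
    "Foraging",
    "Lactating",
    "Scrubbing",
    "Standing",
    "Walking",
    "Other",
)
UNKNOWN: str = "Unknown"
VOCABULARY: tuple[str, ...] = BEHAVIOURS + (UNKNOWN,)

ACCEL_COLUMNS = ("animal_id", "timestamp", "ax", "ay", "az")
LABEL_COLUMNS = ("timestamp", "behaviour")


class EthoaccelError(Exception):
    """Base class for all package errors."""


class FormatError(EthoaccelError):
    """Malformed input file (missing columns, unparseable values)."""


class DuplicateTimestampError(EthoaccelError):
    """Two records share one (animal, timestamp)."""


class MergeError(EthoaccelError):
    """Acceleration and label streams have no timestamps in common."""


class VocabularyError(EthoaccelError):
    """A label is outside the closed behaviour vocabulary."""


class InsufficientDataError(EthoaccelError):
    """Too few samples for the requested operation."""


class ParameterError(EthoaccelError):
    """Invalid parameter value."""


@dataclass(frozen=True)
class AccelSeries:
    """Per-animal triaxial acceleration stream.

    Attributes
    ----------
    animal_id : str
        Opaque animal identifier.
    timestamps : ndarray of int64
        Strictly increasing, in sample periods (seconds at 1 Hz).
    ax, ay, az : ndarray of float64
        Acceleration per axis in sensor units (carried opaquely; the
        transforms are unit-agnostic).
    sampling_rate_hz : float
        Nominal sampling rate, default 1.0.
    """

    animal_id: str
    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sampling_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, dtype=np.int64))
        for name in ("ax", "ay", "az"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = len(self.timestamps)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise FormatError("timestamps and axis arrays must have equal length")
        if self.sampling_rate_hz <= 0:
            raise ParameterError("sampling_rate_hz must be positive")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise DuplicateTimestampError(
                f"timestamps for animal {self.animal_id!r} are not strictly increasing"
            )
        for name in ("ax", "ay", "az"):
            if n and not np.all(np.isfinite(getattr(self, name))):
                raise FormatError(f"non-finite values in column {name!r}")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) array view of the three axes."""
        return np.column_stack([self.ax, self.ay, self.az])

    def segments(self) -> list[slice]:
        """Maximal contiguous runs (inter-sample gap of exactly one period)."""
        n = len(self)
        if n == 0:
            return []
        breaks = np.flatnonzero(np.diff(self.timestamps) != 1) + 1
        bounds = np.concatenate([[0], breaks, [n]])
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    def is_contiguous(self) -> bool:
        return len(self.segments()) <= 1


@dataclass(frozen=True)
class LabelledSeries(AccelSeries):
    """An :class:`AccelSeries` with one behaviour label per record."""

    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        super().__post_init__()
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        if len(self.labels) != len(self.timestamps):
            raise FormatError("labels must have one entry per record")
        _check_vocabulary(self.labels)

    def accel(self) -> AccelSeries:
        """The underlying unlabelled stream."""
        return AccelSeries(
            self.animal_id, self.timestamps, self.ax, self.ay, self.az, self.sampling_rate_hz
        )


def _check_vocabulary(labels: Iterable[str]) -> None:
    bad = sorted({str(b) for b in labels} - set(VOCABULARY))
    if bad:
        raise VocabularyError(
            f"labels outside the behaviour vocabulary: {bad}; valid labels are {list(VOCABULARY)}"
        )


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a delimited text file with auto-detected delimiter."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def read_accel(path: str | Path, sampling_rate_hz: float = 1.0) -> list[AccelSeries]:
    """Read an acceleration CSV/TSV into one :class:`AccelSeries` per animal.

    Expects a header row with columns ``animal_id, timestamp, ax, ay, az``.
    Records are sorted by timestamp per animal; duplicated
    (animal, timestamp) pairs are rejected.
    """
    df = _read_table(path, ACCEL_COLUMNS)
    out: list[AccelSeries] = []
    for animal, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp")
        ts = np.asarray(np.floor(grp["timestamp"].to_numpy(dtype=np.float64)), dtype=np.int64)
        if len(ts) > 1 and np.any(np.diff(ts) == 0):
            raise DuplicateTimestampError(
                f"duplicate timestamps for animal {animal!r} in {path}"
            )
        out.append(
            AccelSeries(
                str(animal),
                ts,
                grp["ax"].to_numpy(dtype=np.float64),
                grp["ay"].to_numpy(dtype=np.float64),
                grp["az"].to_numpy(dtype=np.float64),
                sampling_rate_hz,
            )
        )
    n_seg = sum(len(s.segments()) for s in out)
    logger.info("read %d records, %d animal(s), %d segment(s) from %s", len(df), len(out), n_seg, path)
    return out


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a behaviour-label file (columns ``timestamp, behaviour`` and
    optionally ``animal_id``); truncates timestamps to integers and checks
    the vocabulary."""
    df = _read_table(path, LABEL_COLUMNS)
    df = df.copy()
    df["timestamp"] = np.floor(df["timestamp"].to_numpy(dtype=np.float64)).astype(np.int64)
    df["behaviour"] = df["behaviour"].astype(str)
    _check_vocabulary(df["behaviour"])
    return df


def write_accel(series: AccelSeries | Iterable[AccelSeries], path: str | Path, sep: str = ",") -> None:
    """Write one or more series back to delimited text (round-trips with
    :func:`read_accel`).  Labelled series gain a ``behaviour`` column."""
    if isinstance(series, AccelSeries):
        series = [series]
    frames = []
    for s in series:
        d = {
            "animal_id": s.animal_id,
            "timestamp": s.timestamps,
            "ax": s.ax,
            "ay": s.ay,
            "az": s.az,
        }
        if isinstance(s, LabelledSeries):
            d["behaviour"] = s.labels
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def merge_labels(accel: AccelSeries, labels: pd.DataFrame) -> LabelledSeries:
    """Inner-join an acceleration stream with a (timestamp, behaviour) table.

    Acceleration seconds without a label and labelled seconds without
    acceleration are dropped; the counts of both are logged.  If the label
    table carries an ``animal_id`` column it is filtered to this animal
    first.
    """
    lab = labels
    if "animal_id" in lab.columns:
        lab = lab[lab["animal_id"].astype(str) == accel.animal_id]
    lab = lab.drop_duplicates(subset="timestamp", keep="first")
    _check_vocabulary(lab["behaviour"])

    lookup = dict(zip(lab["timestamp"].astype(np.int64), lab["behaviour"].astype(str)))
    keep = np.array([int(t) in lookup for t in accel.timestamps], dtype=bool)
    if not keep.any():
        raise MergeError(
            f"no overlapping timestamps between acceleration and labels for animal {accel.animal_id!r}"
        )
    dropped_accel = int((~keep).sum())
    dropped_labels = len(lab) - int(keep.sum())
    logger.info(
        "merge %s: kept %d s, dropped %d unlabelled acceleration s, %d labels without acceleration",
        accel.animal_id, int(keep.sum()), dropped_accel, dropped_labels,
    )
    merged_labels = np.array([lookup[int(t)] for t in accel.timestamps[keep]], dtype=object)
    return LabelledSeries(
        accel.animal_id,
        accel.timestamps[keep],
        accel.ax[keep],
        accel.ay[keep],
        accel.az[keep],
        accel.sampling_rate_hz,
        merged_labels,
    )
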