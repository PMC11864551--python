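"""Fixed-length overlapping windows with a majority behaviour per window.

Windows tile each contiguous recording segment from its start with a
fixed stride (50 % overlap by default); the terminal remainder shorter
than one window is discarded.  Windows never span a recording gap.  Each
window carries raw and jerk-filtered channel slices plus the modal
behaviour of its seconds (with the fraction of seconds carrying that
behaviour recorded as ``label_purity``).  Mixed windows are intentional:
assigning the most frequent behaviour mimics the applied situation where
behaviour boundaries are unknown a priori, and the purity lets users
study the resulting label contamination.

Because the jerk channels of a segment are one sample shorter than the
raw channels, the first raw sample of every segment is dropped so all
channels align in one rectangular block per window.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io_core import UNKNOWN, AccelSeries, LabelledSeries, ParameterError
from .signal import angular_change, jerk

logger = logging.getLogger("ethoaccel")

__all__ = ["Window", "WindowSet", "make_windows", "majority_label"]

#: Channel naming convention: raw axes x, y, z; jerk-filtered axes carry a
#: "j" suffix; "dtheta" is the angular-change channel.
RAW_CHANNELS = ("x", "y", "z")
JERK_CHANNELS = ("xj", "yj", "zj")
DEFAULT_CHANNELS = RAW_CHANNELS + JERK_CHANNELS


@dataclass(frozen=True)
class Window:
    animal_id: str
    start_time: int
    channels: dict[str, np.ndarray]
    majority_label: str
    label_purity: float


@dataclass(frozen=True)
class WindowSet:
    """All windows cut from one or more labelled series at one size."""

    window_s: int
    overlap: float
    step_s: int
    sampling_rate_hz: float
    channel_names: tuple[str, ...]
    windows: list[Window] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def samples_per_window(self) -> int:
        return int(round(self.window_s * self.sampling_rate_hz))


def majority_label(labels: np.ndarray | list[str]) -> tuple[str, float]:
    """Modal label of a window and its purity (fraction of seconds).

    Ties are broken by the earliest first occurrence within the window, a
    deterministic and order-stable rule.
    """
    labels = list(labels)
    if not labels:
        raise ParameterError("majority_label requires a non-empty label sequence")
    counts = Counter(labels)
    best = max(counts.values())
    for lab in labels:  # first label reaching the maximal count wins
        if counts[lab] == best:
            return str(lab), best / len(labels)
    raise AssertionError("unreachable")


def window_step(window_samples: int, overlap: float) -> int:
    """Stride in samples for a given window length and overlap fraction."""
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must be in [0, 1)")
    return max(1, int(round(window_samples * (1 - overlap))))


def make_windows(
    series: AccelSeries | list[AccelSeries],
    window_s: int,
    overlap: float = 0.5,
    include_dtheta: bool = False,
    scale_jerk_by_rate: bool = True,
) -> WindowSet:
    """Cut one or more (labelled) series into overlapping windows.

    ``window_s`` times the sampling rate must be an integer of at least 4
    samples.  Unlabelled series (or all-``Unknown`` labels) yield windows
    labelled ``Unknown`` — prediction mode.  A window length exceeding
    every segment produces an empty set with a warning, not an error.
    """
    if isinstance(series, AccelSeries):
        series = [series]
    if not series:
        raise ParameterError("no input series")
    fs = series[0].sampling_rate_hz
    if any(s.sampling_rate_hz != fs for s in series):
        raise ParameterError("all series must share one sampling rate")
    w = window_s * fs
    if abs(w - round(w)) > 1e-9:
        raise ParameterError("window_s x sampling_rate must be an integer number of samples")
    w = int(round(w))
    if w < 4:
        raise ParameterError("window must span at least 4 samples")
    step = window_step(w, overlap)

    channel_names = DEFAULT_CHANNELS + (("dtheta",) if include_dtheta else ())
    out: list[Window] = []
    discarded_s = 0
    for s in series:
        labels = s.labels if isinstance(s, LabelledSeries) else None
        for seg in s.segments():
            xyz = s.xyz[seg]
            length = xyz.shape[0]
            if length < 2:
                discarded_s += length
                continue
            j = jerk(xyz, fs, scale_jerk_by_rate)
            chans = {
                "x": xyz[1:, 0],
                "y": xyz[1:, 1],
                "z": xyz[1:, 2],
                "xj": j[:, 0],
                "yj": j[:, 1],
                "zj": j[:, 2],
            }
            if include_dtheta:
                chans["dtheta"] = angular_change(xyz)
            usable = length - 1  # first raw sample dropped to align with jerk
            ts = s.timestamps[seg][1:]
            seg_labels = labels[seg][1:] if labels is not None else None
            n_win = (usable - w) // step + 1 if usable >= w else 0
            discarded_s += usable - ((n_win - 1) * step + w) if n_win else usable
            for k in range(n_win):
                lo = k * step
                sl = slice(lo, lo + w)
                if seg_labels is None:
                    lab, purity = UNKNOWN, 1.0
                else:
                    lab, purity = majority_label(seg_labels[sl])
                out.append(
                    Window(
                        s.animal_id,
                        int(ts[lo]),
                        {c: chans[c][sl] for c in channel_names},
                        lab,
                        purity,
                    )
                )
    if not out:
        warnings.warn(
            f"window of {window_s}s produced no windows (all segments too short)", stacklevel=2
        )
    per_class = Counter(win.majority_label for win in out)
    logger.info(
        "windows: %d of %d s (step %d s) from %d series; discarded %d terminal sample(s); per class: %s",
        len(out), window_s, int(step / fs), len(series), discarded_s, dict(per_class),
    )
    return WindowSet(window_s, overlap, int(round(step / fs)), fs, channel_names, out)
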