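"""Per-sample transforms: jerk filter, angular change and ODBA.

Ear tags rotate freely on the animal, so the raw axes mix gravity
(posture) with dynamic movement in an orientation-dependent way.  The
jerk filter — the first difference of each axis — removes the static
gravity component entirely and yields orientation-independent movement
channels.  The angle between consecutive acceleration vectors measures
directional change.  ODBA (overall dynamic body acceleration) separates a
static component, estimated by a short centred running mean, from the
dynamic residual and sums the absolute residuals over the three axes; it
is the standard proxy for movement intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import AccelSeries, InsufficientDataError, ParameterError

__all__ = ["JerkSeries", "OdbaSeries", "jerk_filter", "odba", "jerk", "angular_change"]


@dataclass(frozen=True)
class JerkSeries:
    """First-difference (jerk) channels of one contiguous segment.

    One sample shorter than the segment; ``jx[i]`` pairs with raw sample
    ``i + 1``.  ``dtheta`` is the angle in degrees between consecutive 3-D
    acceleration vectors, in [0, 180].
    """

    jx: np.ndarray
    jy: np.ndarray
    jz: np.ndarray
    dtheta: np.ndarray


@dataclass(frozen=True)
class OdbaSeries:
    """ODBA per sample (same length as the input series)."""

    odba: np.ndarray
    smoothing_window_s: int = 3


def jerk(xyz: np.ndarray, sampling_rate_hz: float = 1.0, scale_by_rate: bool = True) -> np.ndarray:
    """First difference of an (n, 3) acceleration block.

    With ``scale_by_rate`` the difference is multiplied by the sampling
    rate, giving a per-second rate of change; at 1 Hz the two conventions
    coincide, which is why either reading of "jerk filter" yields the same
    numbers in the low-rate regime this package targets.
    """
    d = np.diff(np.asarray(xyz, dtype=np.float64), axis=0)
    return d * sampling_rate_hz if scale_by_rate else d


def angular_change(xyz: np.ndarray) -> np.ndarray:
    """Angle (degrees) between consecutive rows of an (n, 3) block.

    Computed with atan2(|a x b|, a . b), which is numerically stable near
    0 and 180 degrees.  Defined as 0 when either vector has zero norm.
    """
    a = np.asarray(xyz, dtype=np.float64)[:-1]
    b = np.asarray(xyz, dtype=np.float64)[1:]
    cross = np.linalg.norm(np.cross(a, b), axis=1)
    dot = np.einsum("ij,ij->i", a, b)
    ang = np.degrees(np.arctan2(cross, dot))
    zero = (np.linalg.norm(a, axis=1) == 0) | (np.linalg.norm(b, axis=1) == 0)
    ang[zero] = 0.0
    return ang


def jerk_filter(segment: AccelSeries, scale_by_rate: bool = True) -> JerkSeries:
    """Jerk channels and angular change for one contiguous segment."""
    if not segment.is_contiguous():
        raise ParameterError("jerk_filter requires a single contiguous segment")
    if len(segment) < 2:
        raise InsufficientDataError("jerk filter needs at least 2 samples")
    j = jerk(segment.xyz, segment.sampling_rate_hz, scale_by_rate)
    return JerkSeries(j[:, 0], j[:, 1], j[:, 2], angular_change(segment.xyz))


def _centred_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average whose window shrinks symmetrically at the
    edges, so a constant input is reproduced exactly everywhere."""
    n = len(values)
    half = window // 2
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate([[0.0], np.cumsum(values)])
    return (csum[idx + h + 1] - csum[idx - h]) / (2 * h + 1)


def odba(series: AccelSeries, smoothing_window_s: int = 3) -> OdbaSeries:
    """Overall dynamic body acceleration with a centred running-mean
    static estimate (default 3-s smoothing window).

    The static component per axis is the centred moving average over the
    smoothing window (shrinking symmetrically at segment edges); the
    dynamic component is the raw signal minus the static one, and ODBA is
    the sum of the absolute dynamic components over the three axes.
    Computed independently per contiguous segment so smoothing never
    crosses a recording gap.
    """
    if smoothing_window_s <= 0:
        raise ParameterError("smoothing window must be a positive number of seconds")
    window = int(round(smoothing_window_s * series.sampling_rate_hz))
    if window < 1:
        raise ParameterError("smoothing window shorter than one sample")
    if window % 2 == 0:
        raise ParameterError("smoothing window must span an odd number of samples")
    out = np.zeros(len(series), dtype=np.float64)
    for seg in series.segments():
        for axis in (series.ax, series.ay, series.az):
            vals = axis[seg]
            out[seg] += np.abs(vals - _centred_mean(vals, window))
    return OdbaSeries(out, smoothing_window_s)
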