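import numpy as np
import pytest

from ethoaccel.io_core import AccelSeries, LabelledSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_series(
    n=100,
    animal_id="a01",
    labels=None,
    gaps=(),
    seed=0,
    fs=1.0,
):
    """A random walk-ish acceleration series with optional timestamp gaps
    (indices after which one extra second is skipped)."""
    rg = np.random.default_rng(seed)
    ts = np.arange(n, dtype=np.int64)
    for g in sorted(gaps):
        ts[g + 1 :] += 5
    ax, ay, az = rg.normal(0, 50, (3, n))
    az += 1000.0
    if labels is None:
        return AccelSeries(animal_id, ts, ax, ay, az, fs)
    return LabelledSeries(animal_id, ts, ax, ay, az, fs, np.asarray(labels, dtype=object))


@pytest.fixture
def series_factory():
    return build_series
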