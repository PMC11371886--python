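import numpy as np
import pytest

from hrvcohort.preprocess import NNSeries
from hrvcohort.synthetic import RRGenParams, gen_chaotic_series, gen_rr_record


@pytest.fixture(scope="session")
def logistic_series():
    return gen_chaotic_series("logistic", (4.0,), 10000, 0.2)


@pytest.fixture(scope="session")
def henon_series():
    return gen_chaotic_series("henon", (1.4, 0.3), 5000)


@pytest.fixture(scope="session")
def short_nn():
    """A clean 30-minute synthetic NN series (no ectopy/artifacts)."""
    rr = gen_rr_record(RRGenParams(duration_h=0.5, seed=101))
    return NNSeries(rr.record_id, rr.intervals, rr.beat_times)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_nn(intervals, times=None):
    intervals = np.asarray(intervals, dtype=float)
    if times is None:
        times = np.cumsum(intervals) / 1000.0
    return NNSeries("test", intervals, times)
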