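import numpy as np
import pytest

from kinemap.signal_core import AccelSeries, ProcessingConfig, decompose_series


@pytest.fixture
def config():
    return ProcessingConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20180)


def make_series(a, participant_id="p1", site="wrist", fs=10.0, t=None):
    a = np.asarray(a, dtype=float)
    if t is None:
        t = np.arange(len(a)) / fs
    return AccelSeries(participant_id=participant_id, sensor_site=site,
                       sample_rate_hz=fs, t=t, a=a)


@pytest.fixture
def random_series(rng):
    """300 samples of gravity + mild movement noise."""
    n = 300
    a = np.tile([0.0, 0.0, 1.0], (n, 1)) + rng.normal(0, 0.15, (n, 3))
    return make_series(a)


@pytest.fixture
def random_decomposed(random_series, config):
    return decompose_series(random_series, config)


def random_rotation(rng):
    """A uniformly random proper 3-D rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
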