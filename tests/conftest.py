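import numpy as np
import pytest

from tumorgrowth import GrowthLawParams, VolumeSeries, gompertz_volume
from tumorgrowth.datasets import xenograft_dose_observations, xenograft_ratio_table


def make_gompertz_series(subject_id="syn", vinf_ratio=0.3, k=0.03, v0=1.0,
                         times=None, noise_rel=0.0, seed=0, law="gompertz"):
    """Synthetic series from known ground truth (multiplicative noise)."""
    if times is None:
        times = np.linspace(0.0, 40.0, 10)
    times = np.asarray(times, dtype=float)
    p = GrowthLawParams(law, V0=v0, Vinf=v0 * vinf_ratio, rate=k)
    volumes = np.asarray(p.volume(times), dtype=float)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        volumes = volumes * np.exp(rng.normal(0.0, noise_rel, volumes.shape))
    return VolumeSeries(subject_id, times, volumes), p


@pytest.fixture(scope="session")
def xeno_observations():
    return xenograft_dose_observations()


@pytest.fixture(scope="session")
def xeno_table():
    return xenograft_ratio_table()


@pytest.fixture
def l3_nt_series():
    """Untreated L3 line: normalized volumes 1, 1.6, 1.9 at days 0, 15, 30."""
    return VolumeSeries("L3-NT", [0.0, 15.0, 30.0], [1.0, 1.6, 1.9],
                        normalization="ratio_to_first")
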