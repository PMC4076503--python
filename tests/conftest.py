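import numpy as np
import pytest
from hypothesis import settings

from mearec import Metadata, Recording, with_summary

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def random_recording(rng, n_units=None, max_spikes=200, with_names=False):
    """A small random valid recording for round-trip / validation tests."""
    n = int(n_units if n_units is not None else rng.integers(1, 20))
    scount = rng.integers(0, max_spikes, size=n)
    if scount.sum() == 0:
        scount[rng.integers(n)] = 1  # duration needs at least one spike
    spikes = np.concatenate(
        [np.sort(rng.uniform(0, 600.0, size=c)) for c in scount]
    )
    rec = Recording(
        epos=rng.uniform(0, 700.0, size=(n, 2)),
        spikes=spikes,
        scount=scount,
        array="MCS_8x8_100um",
        meta=Metadata(
            key="Test2024",
            species="mouse",
            age=int(rng.integers(0, 15)),
            genotype="wt",
            cond="ctl",
        ),
        names=[f"unit{i}" for i in range(n)] if with_names else None,
    )
    return with_summary(rec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_rec():
    """Hand-built three-unit recording with known contents."""
    rec = Recording(
        epos=np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]]),
        spikes=np.array([0.1, 0.9, 0.2, 0.4, 0.8, 0.5]),
        scount=np.array([2, 3, 1]),
        array="MCS_8x8_100um",
        meta=Metadata(key="Test2024", species="mouse", age=5),
    )
    return with_summary(rec)
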