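import numpy as np
import pytest

from ppgemotion.preprocess import PPGRecord, bandpass, smooth
from ppgemotion.windkessel import BASE_PARAMS, simulate

FS = 125.0


@pytest.fixture(scope="session")
def settled_wave():
    """~20 s of settled pulse at the baseline parameter set, 125 Hz."""
    return simulate(BASE_PARAMS, fs=FS, n_cycles=26)


@pytest.fixture(scope="session")
def long_wave():
    """~60 s of settled pulse for fiducial statistics."""
    return simulate(BASE_PARAMS, fs=FS, n_cycles=78)


@pytest.fixture(scope="session")
def clean_record(long_wave):
    """The 60-s pulse train after bandpass and smoothing."""
    return smooth(bandpass(PPGRecord(long_wave.samples, FS, subject_id="fix")))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
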