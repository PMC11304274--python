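import numpy as np
import pytest

from pureshift.simkit import AcquisitionParams, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_acq():
    """Small chunk geometry for fast exact checks: 8 chunks x 16 -> 256."""
    return AcquisitionParams(spectral_width_hz=1000.0, chunk_len=16,
                             n_chunks=8, n_ft=256)


@pytest.fixture
def tiny_sim(tiny_acq):
    return SimConfig(acq=tiny_acq, n_peaks_range=(2, 5),
                     lw_range_hz=(1.0, 8.0))


@pytest.fixture
def default_acq():
    """The reference chunk geometry: 93 chunks x 64 zero-filled to 8192."""
    return AcquisitionParams()
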