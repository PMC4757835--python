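import numpy as np
import pytest

from kinetex import phantom
from kinetex.core import RoiMask


@pytest.fixture(scope="session")
def acq():
    return phantom.AcquisitionParams()


@pytest.fixture(scope="session")
def lesion(acq):
    """One moderately heterogeneous lesion with default (2%) noise."""
    return phantom.make_lesion(seed=7, radius_mm=5.0, spiculation=0.15,
                               heterogeneity=0.3, mean_ktrans=0.2, ve=0.4,
                               acq=acq)


@pytest.fixture(scope="session")
def noiseless_lesion():
    acq0 = phantom.AcquisitionParams(noise_sd=0.0)
    return phantom.make_lesion(seed=3, radius_mm=5.0, spiculation=0.1,
                               heterogeneity=0.2, mean_ktrans=0.25, ve=0.4,
                               acq=acq0)


@pytest.fixture()
def disk_mask():
    yy, xx = np.mgrid[0:41, 0:41]
    return RoiMask((yy - 20) ** 2 + (xx - 20) ** 2 <= 15 ** 2)
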