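import numpy as np
import pytest

from spectraseg.dataio import simulate_dataset
from spectraseg.phantom import AcquisitionParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Three small scans (32x32, 2 slices) with a manifest, for IO/training."""
    out = tmp_path_factory.mktemp("tinydata")
    acq = AcquisitionParams(image_size=32, n_slices=2, seed=7)
    manifest = simulate_dataset(3, acq, out)
    return out, manifest
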