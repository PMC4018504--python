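import numpy as np
import pytest

import chemography as cg


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian blobs in 5-D."""
    return cg.gaussian_classes(n_per_class=(60, 60), dim=5, separation=6.0, seed=1)


@pytest.fixture(scope="session")
def small_gtm(blob_data):
    return cg.fit_gtm(blob_data.X, K=16, M=4, seed=0, max_iter=50)


@pytest.fixture(scope="session")
def swiss_roll():
    data, unrolled = cg.labeled_swiss_roll(n=400, noise=0.05, seed=0)
    return data, unrolled


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
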