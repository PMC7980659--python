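import numpy as np
import pytest

import skinperm as sp


@pytest.fixture(scope="session")
def ppm_df():
    """Default-condition synthetic partitioning dataset (n=175, sigma=0.47)."""
    return sp.generate_ppm_dataset(seed=1)


@pytest.fixture(scope="session")
def gcgc_df():
    """Default-condition synthetic GC x GC dataset (n=79, sigma=0.23)."""
    return sp.generate_gcgc_dataset(seed=1)


@pytest.fixture(scope="session")
def asd_df():
    """Synthetic 175 x 5 Abraham-descriptor matrix."""
    return sp.generate_asd_matrix(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
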