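import numpy as np
import pytest

from dreamscreen import SyntheticConfig, make_bundle, pvalue_table
from dreamscreen.synthetic import default_pfm


@pytest.fixture(scope="session")
def matrix():
    return default_pfm()


@pytest.fixture(scope="session")
def ptable(matrix):
    return pvalue_table(matrix)


@pytest.fixture(scope="session")
def zero_noise_bundle(tmp_path_factory):
    """A deterministic noise-free study: 200 genes, 60 planted true targets."""
    cfg = SyntheticConfig(seed=1, noise_sd=0.0)
    return make_bundle(cfg, tmp_path_factory.mktemp("bundle_zero"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230)
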