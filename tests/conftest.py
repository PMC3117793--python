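import numpy as np
import pytest

import pinnasonar as ps


@pytest.fixture(scope="session")
def head_config():
    return ps.SyntheticHeadConfig()


@pytest.fixture(scope="session")
def partition256():
    return ps.partition_hemisphere(256)


@pytest.fixture(scope="session")
def partition64():
    return ps.partition_hemisphere(64)


@pytest.fixture(scope="session")
def partition16():
    return ps.partition_hemisphere(16)


@pytest.fixture(scope="session")
def cov_default():
    return ps.build_covariance()


@pytest.fixture(scope="session")
def templates64(head_config, partition64):
    """Template set on a coarse partition at 60 kHz (fast unit-test size)."""
    em, hl, hr = ps.synthetic_head_fields(head_config, 60.0, partition64)
    return ps.build_templates(em, hl, hr)


@pytest.fixture
def rng():
    return np.random.default_rng(20110617)
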