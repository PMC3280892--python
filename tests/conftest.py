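import numpy as np
import pytest

from stochsync import (compute_prc, find_limit_cycle, preset)


@pytest.fixture(scope="session")
def ei_spec():
    """E-I preset in its oscillatory regime (sigma = 0.08, symmetric chi)."""
    return preset("ei")


@pytest.fixture(scope="session")
def ei_cycle(ei_spec):
    return find_limit_cycle(ei_spec)


@pytest.fixture(scope="session")
def ei_prc(ei_spec, ei_cycle):
    return compute_prc(ei_cycle, ei_spec)


@pytest.fixture(scope="session")
def dep_spec():
    return preset("depression")


@pytest.fixture(scope="session")
def dep_cycle(dep_spec):
    return find_limit_cycle(dep_spec)


@pytest.fixture(scope="session")
def dep_prc(dep_spec, dep_cycle):
    return compute_prc(dep_cycle, dep_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
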