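import numpy as np
import pytest

from gtbart.group_data import AssayAccuracy, GroupTestingData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dorfman_small():
    """Hand-built well-formed Dorfman-style dataset: N=6, one positive
    master pool with retests, one negative master pool."""
    rng = np.random.default_rng(7)
    X = rng.uniform(0, 10, size=(6, 3))
    pools = [np.array([0, 1, 2]), np.array([3, 4, 5]),
             np.array([0]), np.array([1]), np.array([2])]
    Z = np.array([1, 0, 1, 0, 0], dtype=np.int8)
    stratum = np.array([0, 0, 1, 1, 1])
    return GroupTestingData(X=X, Z=Z, pools=pools, stratum=stratum)


@pytest.fixture
def acc_two_strata():
    return AssayAccuracy.fixed([0.95, 0.98], [0.98, 0.99])
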