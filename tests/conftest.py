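import numpy as np
import pytest

from hetmctp import AncovaData, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20250918)


@pytest.fixture
def welch_pair():
    return make_fixture("welch_pair", seed=3)


@pytest.fixture
def three_group():
    return make_fixture("three_group", seed=5)


@pytest.fixture
def nine_point():
    """Tiny fixed dataset: N=9, a=3, one covariate, written out by hand so
    oracle computations can be done from first principles."""
    y = np.array([2.1, 3.0, 4.2, 5.1, 6.3, 6.9, 9.0, 10.2, 11.1])
    groups = np.repeat(["g1", "g2", "g3"], 3)
    cov = np.arange(1.0, 10.0).reshape(-1, 1)
    return AncovaData(y=y, groups=groups, covariates=cov)
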