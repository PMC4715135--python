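import numpy as np
import pytest

from discod import DiscreteJointModel, PriorSpec, SampleCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20160115)


@pytest.fixture
def toy_prior():
    """d=1 prior with alpha = beta = 2^d + 1 and flat Dirichlet weights."""
    return PriorSpec(3.0, 3.0, [1.0, 1.0], [1.0, 1.0])


@pytest.fixture
def toy_counts():
    """d=1 counts of the sample {(0,0), (0,0), (1,1), (1,1)}."""
    return SampleCounts(1, [2, 0], [0, 2])


@pytest.fixture
def weak_model():
    """d=1 model with true CoD = 0.2."""
    return DiscreteJointModel(1, 0.5, [0.6, 0.4], [0.4, 0.6])


def random_model(rng, d, dirichlet_conc=1.0, c_range=(0.05, 0.95)):
    ncells = 2**d
    return DiscreteJointModel(
        d,
        float(rng.uniform(*c_range)),
        rng.dirichlet(np.full(ncells, dirichlet_conc)),
        rng.dirichlet(np.full(ncells, dirichlet_conc)),
    )
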