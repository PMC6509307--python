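import numpy as np
import pytest

from ratemoments import (
    FICurveParams,
    NetworkSpec,
    sample_network,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def uncoupled_pair():
    """Two uncoupled cells with correlated noise and analytic moments."""
    return NetworkSpec(
        n_cells=2,
        tau=[1.0, 1.0],
        mu_bg=[0.3, -0.2],
        sigma_bg=[1.0, 1.0],
        corr=[[1.0, 0.5], [0.5, 1.0]],
        coupling=np.zeros((2, 2)),
        fi=(FICurveParams(0.0, 0.2), FICurveParams(0.1, 0.3)),
    )


@pytest.fixture
def weak_triplet():
    """A weakly coupled 3-cell network drawn from the reference distributions."""
    return sample_network(3, coupling_scale=1.0, seed=11)


@pytest.fixture
def single_cell():
    return NetworkSpec(
        n_cells=1,
        tau=[1.0],
        mu_bg=[0.8],
        sigma_bg=[1.0],
        corr=[[1.0]],
        coupling=[[0.0]],
        fi=(FICurveParams(0.0, 0.2),),
    )
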