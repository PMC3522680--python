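import numpy as np
import pytest

from mtglasso.simulate import SimulationDesign, simulate_dataset
from mtglasso.stacking import MultiResponseData, orthonormalize, stack


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_signal_dataset():
    """n=120, p=40 dataset with 12 causal SNPs in three clusters."""
    design = SimulationDesign(
        n=120,
        p=40,
        q=2,
        rho=0.5,
        causal_clusters=((4, 5, 6, 7), (14, 15, 16, 17), (24, 25, 26, 27)),
        effect_size=0.5,
        seed=11,
    )
    return simulate_dataset(design)


@pytest.fixture
def random_data(rng):
    """Unstructured 30x6, q=2 dataset for algebraic checks."""
    G = rng.integers(0, 3, size=(30, 6))
    G[0] = [0, 1, 2, 0, 1, 2]  # guarantee variation
    G[1] = [2, 0, 1, 2, 0, 1]
    Y = rng.normal(size=(30, 2))
    return MultiResponseData(G, Y)


@pytest.fixture
def stacked_basis(random_data):
    stacked = stack(random_data)
    return stacked, orthonormalize(stacked)
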