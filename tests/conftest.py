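import numpy as np
import pytest

from robustbg.simulate import ShoeboxSpec, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160901)


@pytest.fixture(scope="session")
def weak_dataset_25px():
    """10^4 shoeboxes with 25 background pixels at lambda = 0.15.

    5x5 grids with no foreground: the photon-counting regime where the
    background is dominated by 0- and 1-count pixels.
    """
    spec = ShoeboxSpec(width=5, height=5, background=0.15, foreground_radius=0.0)
    return simulate_dataset(10_000, spec, seed=150)
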