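import numpy as np
import pytest

from tomodenoise.experiments import SyntheticStudy, simulate_split_study
from tomodenoise.io import Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_volume(rng) -> Volume3D:
    return Volume3D(rng.normal(size=(32, 32, 32)))


@pytest.fixture(scope="session")
def study() -> SyntheticStudy:
    """One shared synthetic acquisition (phantom, tilt series, split FBPs)."""
    return simulate_split_study(seed=0)
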