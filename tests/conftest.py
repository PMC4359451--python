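import numpy as np
import pytest

from exocall.experiments import CohortData, prepare
from exocall.simulate import SimConfig


@pytest.fixture(scope="session")
def small_data() -> CohortData:
    """A small cohort shared by unit tests: 40 samples, 200 target sites."""
    cfg = SimConfig(
        n_samples=40,
        n_target_sites=200,
        n_flank_markers=48,
        n_targets=4,
        seed=7,
    )
    return prepare(cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
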