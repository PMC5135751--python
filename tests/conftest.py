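import numpy as np
import pytest

from tnfigrs.config import SimulationConfig
from tnfigrs.synthetic_cohort import generate_cohort


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study reused by read-only tests."""
    cfg = SimulationConfig(seed=11, n_cases=150, n_controls=200, n_panel_snps=60)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
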