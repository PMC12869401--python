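import numpy as np
import pytest

from cortexage import build_hierarchy
from cortexage.simulate import SimulationConfig, end_to_end_fixture


@pytest.fixture(scope="session")
def hierarchy_012():
    """Two-hemisphere atlas hierarchy at subdivision levels 0, 1, 2."""
    return build_hierarchy((0, 1, 2))


@pytest.fixture(scope="session")
def e2e():
    """Full pipeline run on the reference synthetic cohort.

    400 subjects, levels (0, 1, 2), a quarter of subjects carrying a +10 y
    accelerated-aging lesion in region 0; controls-only training with the
    lesioned subgroup held out.  Shared across integration and acceptance
    tests because training is the slow step.
    """
    cfg = SimulationConfig(lesion_fraction=0.25, seed=0)
    return end_to_end_fixture(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
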