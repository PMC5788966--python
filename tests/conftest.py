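import numpy as np
import pytest

from nirsdecode.montage import build_default_montage
from nirsdecode.synth import GeneratorConfig, simulate_session


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


@pytest.fixture(scope="session")
def clean_session(montage):
    """Artifact-free default session (internals kept for recovery checks)."""
    cfg = GeneratorConfig(seed=2, artifact_rate_per_min=0.0,
                          shift_rate_per_min=0.0)
    return simulate_session(cfg, montage)


@pytest.fixture(scope="session")
def default_session(montage):
    """Default session with motion artifacts enabled."""
    return simulate_session(GeneratorConfig(seed=3), montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
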