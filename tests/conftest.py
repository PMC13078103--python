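import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ringdemog.experiments import ExperimentConfig, run_recovery
from ringdemog.synth import gen_site_gradient

settings.register_profile(
    "suite", derandomize=True, max_examples=60, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

#: Seed used for the shared full-scale experiment; fixed so that every test
#: observing the run sees the same realisation.
GRADIENT_SEED = 1


@pytest.fixture(scope="session")
def gradient() -> "SiteGradient":
    return gen_site_gradient()


@pytest.fixture(scope="session")
def gradient_run():
    """Full-scale recovery experiment: 5 sites x 3 modes x 30 members x 25 patches x 300 years."""
    cfg = ExperimentConfig()
    return cfg, run_recovery(cfg, seed=GRADIENT_SEED)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
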