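import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import labelsim as ls

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def builtin():
    return ls.builtin_scenarios()


@pytest.fixture(scope="session")
def small_population():
    """A modest population reused by read-only tests."""
    cfg = ls.PopulationConfig(size=5_000)
    return cfg, ls.generate_population(cfg, seed=42)


@pytest.fixture(scope="session")
def small_run(builtin):
    """A small paired Monte Carlo run reused by read-only driver tests."""
    scen = builtin.subset(["baseline", "mandatory_TLL", "mandatory_NWL"])
    cfg = ls.RunConfig(master_seed=11, n_iterations=4,
                       population=ls.PopulationConfig(size=4_000))
    return cfg, scen, ls.Microsimulation(cfg, scen).run()


def rng(seed=0):
    return np.random.default_rng(seed)
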