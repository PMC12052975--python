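import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gatekeeper as gk

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def double_well_landscape():
    return gk.make_landscape("double_well", {"barrier": 12.0, "minima": 0.8})


@pytest.fixture(scope="session")
def metad_run_medium(double_well_landscape):
    """A medium 4-walker well-tempered run on the 12 kJ/mol double well,
    shared by the metadynamics property tests."""
    cfg = gk.MetadynamicsConfig()
    return gk.run_wt_metadynamics(
        double_well_landscape, cfg, gk.LangevinParams(), gk.WallSpec(),
        n_steps_per_walker=200_000, seed=42), cfg
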