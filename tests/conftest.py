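import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lipoml.synthetic import GeneratorConfig, generate_library

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_library():
    """One default synthetic library (218 formulations, default noise)."""
    return generate_library(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def noise_free_library():
    """Noise-free limit: every measurement equals its ground-truth mean."""
    cfg = GeneratorConfig(noise_cv_diameter=0.0, noise_sd_pdi=0.0, drift_rate=0.0, seed=3)
    return generate_library(cfg)


@pytest.fixture(scope="session")
def small_grid_config():
    """A reduced 32-formulation grid for fast end-to-end runs."""
    from lipoml.datamodel import SynthesisParams

    combos = tuple(
        SynthesisParams(tfr, lipid, ratio, curc)
        for curc in (False, True)
        for tfr in (1, 2, 4, 8)
        for lipid in (10, 40)
        for ratio in (3, 9)
    )
    return dict(combinations=combos)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
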