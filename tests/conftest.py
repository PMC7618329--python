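import numpy as np
import pytest
from hypothesis import settings

from aqhimix.simulate import SimulationConfig, generate_city

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def city_3yr():
    """One deterministic 3-year city with the default mixture effect."""
    cfg = SimulationConfig(years=3, seed=42)
    return generate_city(cfg, 0)


@pytest.fixture(scope="session")
def city_null_3yr():
    """3-year city with no pollutant effect on mortality."""
    cfg = SimulationConfig(years=3, seed=42, effect_mode="none")
    return generate_city(cfg, 0)


@pytest.fixture(scope="session")
def small_panel():
    """Four 3-year cities (complete exposures, no heterogeneity in truth)."""
    cfg = SimulationConfig(
        n_cities=4, years=3, seed=7,
        missing_rates=(0.0, 0.0, 0.0, 0.0),
    )
    return [generate_city(cfg, i) for i in range(cfg.n_cities)]
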