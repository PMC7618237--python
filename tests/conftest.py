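import numpy as np
import pytest

from ncd_decomp import AgeGrid, ScenarioConfig, generate_surface


@pytest.fixture(scope="session")
def grid():
    return AgeGrid.default()


@pytest.fixture(scope="session")
def three_year_result():
    """Default 24-country scenario at the three analysis years."""
    return generate_surface(ScenarioConfig(years=(2001, 2010, 2019), seed=11))


@pytest.fixture(scope="session")
def counts_result():
    """Small count-bearing scenario for draw-based uncertainty tests."""
    cfg = ScenarioConfig(
        regions=("high_income_western",),
        n_countries_per_region=2,
        years=(2010, 2019),
        with_counts=True,
        population_median=4e5,
        population_sigma=0.2,
        seed=13,
    )
    return generate_surface(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
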