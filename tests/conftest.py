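import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from excessscan.standardize import StandardPopulation, add_adjusted_rate
from excessscan.synthetic import SimConfig, generate_units, simulate_deaths

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def who_std() -> StandardPopulation:
    return StandardPopulation.who_world()


@pytest.fixture(scope="session")
def small_units(who_std) -> pd.DataFrame:
    """120 simulated units with deaths and age-standardized rates."""
    cfg = SimConfig(n_units=120, n_covariates=10, seed=7)
    units = simulate_deaths(generate_units(cfg), cfg)
    return add_adjusted_rate(units, who_std)


def toy_grid(n: int, seed: int = 0, pop_low: int = 500, pop_high: int = 5000) -> pd.DataFrame:
    """A tiny unit table on a planar-ish grid with random rates, for scan tests."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "unit_id": [f"T{i:03d}" for i in range(n)],
            "lat": rng.uniform(-2, 2, n),
            "lon": rng.uniform(-2, 2, n),
            "population": rng.integers(pop_low, pop_high, n).astype(float),
            "adjusted_rate": rng.uniform(50, 150, n),
            "predicted_rate": rng.uniform(50, 150, n),
        }
    )
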