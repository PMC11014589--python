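import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("fixed", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("fixed")

# The two-observer worked example: lambda plus bilateral map areas (mm²).
TABLE2 = pd.DataFrame(
    {
        "observer": ["O1", "O2"],
        "lambda": [748.0, 302.0],
        "V1": [3052.0, 2580.0],
        "V2": [2767.0, 2815.0],
        "V3": [2053.0, 1907.0],
        "V4": [1483.0, 618.0],
    }
)


@pytest.fixture
def table2_cohort() -> pd.DataFrame:
    return TABLE2.copy()


def make_random_cohort(seed: int, n: int = 20) -> pd.DataFrame:
    """Generic positive cohort with a partly conserved V4 (for oracle tests)."""
    rng = np.random.default_rng(seed)
    lam = rng.lognormal(mean=6.0, sigma=0.3, size=n)
    cohort = pd.DataFrame({"observer": [f"R{i:02d}" for i in range(n)], "lambda": lam})
    cohort["V4"] = lam * 1.85 * rng.lognormal(0, 0.2, n)
    for m, med in zip(("V1", "V2", "V3"), (2800, 2790, 1980)):
        cohort[m] = med * rng.lognormal(0, 0.15, n)
    return cohort


@pytest.fixture
def random_cohort() -> pd.DataFrame:
    return make_random_cohort(seed=42)


@pytest.fixture(scope="session")
def default_observers():
    from corticalcrowding.synthetic import PopulationParams, generate_population

    return generate_population(PopulationParams(seed=0))


@pytest.fixture(scope="session")
def default_cohort(default_observers) -> pd.DataFrame:
    from corticalcrowding.synthetic import cohort_from_observers

    return cohort_from_observers(default_observers)
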