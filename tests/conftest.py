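import numpy as np
import pandas as pd
import pytest

from mddkit.cohort import FOOD_GROUPS
from mddkit.synthetic import ScenarioConfig, generate_cohort, preset_scenarios


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """A modest heterogeneity-free scenario usable for exact oracles."""
    return ScenarioConfig(
        n_clusters=30,
        children_per_cluster=15,
        n_strata=3,
        weight_dispersion=0.4,
        bf_logit_intercept=3.0,
        bf_logit_slope=-0.12,
        group_logit_intercepts=(0.5, -1.0, -0.5, -1.2, -2.0, -0.2, -0.8),
        group_logit_slope=0.08,
        child_heterogeneity_sd=0.0,
        label="small",
    ).validate()


@pytest.fixture(scope="session")
def small_cohort(small_scenario) -> pd.DataFrame:
    return generate_cohort(small_scenario, seed=42)


@pytest.fixture(scope="session")
def presets():
    return preset_scenarios()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231114)


def random_cohort(rng: np.random.Generator, n: int = 1000) -> pd.DataFrame:
    """An unstructured random cohort for invariant checks."""
    cohort = pd.DataFrame(
        {
            "child_id": np.arange(1, n + 1),
            "cluster_id": rng.integers(1, 21, size=n),
            "stratum_id": 1,
            "weight": rng.gamma(4.0, 0.25, size=n),
            "age_months": rng.integers(6, 24, size=n),
            "breastfed": rng.integers(0, 2, size=n),
        }
    )
    for g in FOOD_GROUPS:
        cohort[g] = rng.integers(0, 2, size=n)
    return cohort
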