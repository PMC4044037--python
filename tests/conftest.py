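import numpy as np
import pytest

from neacod.structures import AgeStructure, Covariates, ParameterSet
from neacod.synthetic import ScenarioConfig, generate_dataset, small_test_scenario


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def small_dataset():
    """One reduced dataset (15 years, ages 1-6) shared across tests."""
    cfg = small_test_scenario(seed=42)
    state, obs, truth = generate_dataset(cfg)
    return cfg, state, obs, truth


@pytest.fixture(scope="session")
def default_dataset():
    """Full-scale synthetic dataset at the default study conditions."""
    cfg = ScenarioConfig(seed=7)
    state, obs, truth = generate_dataset(cfg)
    return cfg, state, obs, truth


@pytest.fixture
def flat_covariates():
    """Constant covariates for analytic checks: w=1 kg, fully mature, T=0."""
    def make(structure: AgeStructure, w=1.0, p=1.0, T=0.0) -> Covariates:
        A, Y = structure.max_age, structure.n_years
        return Covariates(weight=np.full((A, Y), w), maturity=np.full((A, Y), p),
                          temperature=np.full(Y, T))
    return make
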