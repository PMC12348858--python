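import numpy as np
import pytest

from biomass_tradeoff import GeneratorConfig, generate_survey
from biomass_tradeoff.tradeoff import tradeoff_table


@pytest.fixture(scope="session")
def default_table():
    """One default survey table (63 sites x 3 plots x 5 quadrats, seed 0)."""
    return generate_survey(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def scored_table(default_table):
    return tradeoff_table(default_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
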