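import numpy as np
import pytest

from metabotrend.synthetic_data import (
    GeneratorConfig,
    default_compound_universe,
    generate,
    worked_example_fixture,
)


@pytest.fixture(scope="session")
def universe():
    return default_compound_universe()


@pytest.fixture(scope="session")
def small_universe(universe):
    """~200-compound slice for fast pipeline-level tests."""
    return universe.iloc[:200].reset_index(drop=True)


@pytest.fixture(scope="session")
def worked():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def small_dataset(small_universe):
    """One-organ, both-sex dataset with the default trend structure."""
    cfg = GeneratorConfig(seed=7, organs=("plasma", "liver"),
                          compounds=small_universe)
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
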