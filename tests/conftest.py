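import numpy as np
import pytest

from syncosim import datasets
from syncosim.model import ModelContext
from syncosim.params import LifeTable


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return datasets.default_life_table()


@pytest.fixture(scope="session")
def flat_life_table() -> LifeTable:
    """Zero-mortality table covering any model age."""
    return LifeTable([0.0, 120.0], [0.0, 0.0])


@pytest.fixture(scope="session")
def clinical3():
    return datasets.base_clinical(horizon_years=3.0)


@pytest.fixture(scope="session")
def clinical30():
    return datasets.base_clinical(horizon_years=30.0)


@pytest.fixture(scope="session")
def costs():
    return datasets.base_costs()


@pytest.fixture(scope="session")
def profiles():
    return datasets.scenario_profiles()


@pytest.fixture(scope="session")
def ctx3() -> ModelContext:
    return ModelContext.base_case(horizon_years=3.0)


@pytest.fixture(scope="session")
def ctx30() -> ModelContext:
    return ModelContext.base_case(horizon_years=30.0)


@pytest.fixture(scope="session")
def base_result3(ctx3):
    return ctx3.run()


@pytest.fixture(scope="session")
def base_result30(ctx30):
    return ctx30.run()
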