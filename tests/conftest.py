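import pytest

from dmocea import (CostUtilityModel, ModelConfig, build_default_registry,
                    build_default_strategies, synth_life_table)


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def strategies(registry):
    return build_default_strategies(registry)


@pytest.fixture(scope="session")
def life_table():
    return synth_life_table()


@pytest.fixture(scope="session")
def model():
    return CostUtilityModel()


@pytest.fixture(scope="session")
def fitted(model):
    """Deterministic base-case results for all eleven strategies."""
    return model.fit()


@pytest.fixture()
def config():
    return ModelConfig()
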