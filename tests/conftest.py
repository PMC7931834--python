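import pytest
from hypothesis import settings

from vlcost import ViralLoadScaleUpModel, default_config

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def zambia_config():
    return default_config()


@pytest.fixture(scope="session")
def zambia_model(zambia_config):
    return ViralLoadScaleUpModel.from_config(zambia_config, seed=1)


@pytest.fixture(scope="session")
def model_results(zambia_model):
    return zambia_model.fit(mode="model")


@pytest.fixture(scope="session")
def golden_results(zambia_model):
    return zambia_model.fit(mode="golden")
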