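import warnings

import pytest
from hypothesis import settings as hsettings

from silatro_cea import load_config

hsettings.register_profile("ci", derandomize=True, max_examples=50)
hsettings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    with warnings.catch_warnings():
        # two published rows have PSA means slightly off their deterministic
        # values; the loader warns by design
        warnings.simplefilter("ignore")
        return load_config()


@pytest.fixture(scope="session")
def settings(config):
    return config[0]


@pytest.fixture(scope="session")
def adult_params(config):
    return config[1]["adults_adolescents"]


@pytest.fixture(scope="session")
def child_params(config):
    return config[1]["children"]
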