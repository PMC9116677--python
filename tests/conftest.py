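import pytest

from rbpnoise.params import default_params


@pytest.fixture(scope="session")
def params():
    """Bundled fitted parameter set: (dose_response, growth_coupling, noise)."""
    return default_params()


@pytest.fixture(scope="session")
def dp(params):
    return params[0]


@pytest.fixture(scope="session")
def gp(params):
    return params[1]


@pytest.fixture(scope="session")
def npar(params):
    return params[2]
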