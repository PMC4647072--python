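import pytest

from sulfosim import constant_weather, load_fixture, simulate


@pytest.fixture(scope="session")
def hs_config():
    return load_fixture("hs_exp1")


@pytest.fixture(scope="session")
def ls_config():
    return load_fixture("ls_exp1")


@pytest.fixture(scope="session")
def weather60():
    return constant_weather(60, t_min=10.0, t_max=20.0, par=5.0)


@pytest.fixture(scope="session")
def hs_trajectory(hs_config, weather60):
    params, init = hs_config
    return simulate(weather60, init, params)


@pytest.fixture(scope="session")
def ls_trajectory(ls_config, weather60):
    params, init = ls_config
    return simulate(weather60, init, params)
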