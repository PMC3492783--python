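import pytest

import monogyny as mg


@pytest.fixture(scope="session")
def default_params():
    return mg.default_parameters()


@pytest.fixture(scope="session")
def default_eq(default_params):
    """Converged equilibrium at the default parameters (shared; expensive)."""
    eq = mg.solve(default_params)
    assert eq.converged
    return eq


@pytest.fixture(scope="session")
def uniform_env(default_params):
    """Environment induced by the uniform resident at defaults."""
    return mg.build_environment(mg.Strategy.uniform(default_params.t_max), default_params)
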