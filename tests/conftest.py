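import pytest

import renalcea as rc


@pytest.fixture(scope="session")
def baseline() -> rc.ParameterSet:
    """Baseline parameter set (published input values)."""
    return rc.default_parameter_set()


@pytest.fixture(scope="session")
def life_table() -> rc.LifeTable:
    """Synthetic Gompertz life table fitted to ~21 residual years at 62."""
    return rc.default_life_table()
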