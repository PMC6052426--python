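import pytest

from vtece import base_case_parameters, make_life_table


@pytest.fixture(scope="session")
def base_params():
    return base_case_parameters()


@pytest.fixture(scope="session")
def flat_life_table():
    """Constant annual mortality of 1.2% at every age, both sexes."""
    rows = [(age, sex, 0.012) for age in range(18, 111) for sex in ("M", "F")]
    return make_life_table(rows=rows)
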