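import pytest

from lsffcost import (
    build_fixture,
    formulation_from_spec,
    project,
    total_program_cost,
)


@pytest.fixture(scope="session")
def nigeria():
    return build_fixture("nigeria")


@pytest.fixture(scope="session")
def nigeria_formulation(nigeria):
    return formulation_from_spec(nigeria.premix)


@pytest.fixture(scope="session")
def nigeria_demand(nigeria):
    return project(nigeria)


@pytest.fixture(scope="session")
def nigeria_report(nigeria):
    return total_program_cost(nigeria)
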