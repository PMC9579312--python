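import numpy as np
import pytest

import ptupbpk as pk


@pytest.fixture(scope="session")
def adult():
    return pk.age_group_defaults("adult")


@pytest.fixture(scope="session")
def compound():
    return pk.ptu()


@pytest.fixture(scope="session")
def adult_50mg_result(adult, compound):
    """Adult template, 50 mg oral, default (dense) grid — shared across tests."""
    model = pk.build_model(adult, compound)
    return pk.simulate(model, pk.SimulationConfig(dose=50.0))


@pytest.fixture(scope="session")
def adult_50mg_pk(adult_50mg_result):
    return pk.nca(adult_50mg_result.profile())
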