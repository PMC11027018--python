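import pytest

from etqsp import reference_model


@pytest.fixture(scope="session")
def model():
    """Shared reference model; kinetic and steady-state caches persist."""
    return reference_model()


@pytest.fixture(scope="session")
def kin_params(model):
    return model.kinetics


@pytest.fixture(scope="session")
def cr_params(model):
    return model.cardiorenal


@pytest.fixture(scope="session")
def baseline_occ(model):
    return model.baseline_occupancies()
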