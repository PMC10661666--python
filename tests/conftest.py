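import pytest

from hpcsi import (AcquisitionParams, ChamberLayout, SpeciesSet,
                   make_fixture, run_pipeline)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def layout():
    return ChamberLayout()


@pytest.fixture(scope="session")
def species():
    return SpeciesSet.pyruvate_decarboxylation()


@pytest.fixture(scope="session")
def minimal_result():
    return run_pipeline(make_fixture("two-chamber-minimal"))


@pytest.fixture(scope="session")
def noiseless_result():
    return run_pipeline(make_fixture("noiseless-kinetics"))


@pytest.fixture(scope="session")
def paper_default_result():
    return run_pipeline(make_fixture("paper-default"))


@pytest.fixture()
def volume_pairs():
    # injected/recovered means of the four device loading experiments (uL)
    return [(1000.0, 59.0), (1400.0, 108.0), (1800.0, 154.0), (2200.0, 191.0)]
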