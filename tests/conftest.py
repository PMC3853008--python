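import pytest

from dmpolicy import calibrate, run_scenarios


@pytest.fixture(scope="session")
def calib():
    """Calibrated base-case model (solved once per session)."""
    return calibrate()


@pytest.fixture(scope="session")
def base_runs(calib):
    """The five base-case scenario projections, 2007-2030."""
    return run_scenarios(calib)
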