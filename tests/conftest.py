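import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dissectlpm as d
from dissectlpm.waveforms import PeriodicWaveform

settings.register_profile(
    "repro", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def inflow():
    """The default pulsatile study inflow (1 s period)."""
    return d.synth_inflow()


@pytest.fixture(scope="session")
def peripheral(inflow):
    return d.default_peripheral(inflow)


@pytest.fixture(scope="session")
def model_s44(peripheral):
    return d.build_scenario_model("S_4,4", peripheral)


@pytest.fixture(scope="session")
def model_s1010(peripheral):
    return d.build_scenario_model("S_10,10", peripheral)


@pytest.fixture(scope="session")
def constant_inflow():
    return PeriodicWaveform(np.full(100, 50.0), 1.0, "flow")


@pytest.fixture(scope="session")
def result_s44(model_s44, inflow):
    res = d.simulate(model_s44, inflow)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def result_s1010(model_s1010, inflow):
    res = d.simulate(model_s1010, inflow)
    assert res.converged
    return res
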