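import logging

import pytest
from hypothesis import HealthCheck, settings

import kmrecover as kr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

logging.getLogger("kmrecover").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def aml_ipd():
    return [kr.IPDRecord(t, s) for t, s in kr.load_aml_maintained()]


@pytest.fixture(scope="session")
def aml_curve(aml_ipd):
    curve, truth = kr.km_estimate(aml_ipd)
    return curve


@pytest.fixture(scope="session")
def aml_truth(aml_ipd):
    _, truth = kr.km_estimate(aml_ipd)
    return truth


@pytest.fixture(scope="session")
def paper_calib():
    """The worked axis geometry: 144-pt x-axis for t in [0, 5], 108-pt
    y-axis for S in [0, 1], vertical device coordinates from the top."""
    return kr.calibrate(((72.0, 0.0), (216.0, 5.0)), ((360.0, 0.0), (252.0, 1.0)))
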