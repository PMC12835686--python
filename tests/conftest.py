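import pytest

from cerebroflow.calibration import run_control_calibration
from cerebroflow.network import apply_occlusion, build_network
from cerebroflow.waveform import build_control_waveform


@pytest.fixture(scope="session")
def network():
    return build_network()


@pytest.fixture(scope="session")
def occluded_network(network):
    return apply_occlusion(network, "MCA_l")


@pytest.fixture(scope="session")
def control_waveform():
    return build_control_waveform()


@pytest.fixture(scope="session")
def control_state(network):
    return run_control_calibration(network)
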