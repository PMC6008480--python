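import pytest

from memstdp import NeuronParams, PlasticityParams


@pytest.fixture
def plast():
    """Calibrated plasticity table with the per-ms leak reading used in
    the single-event examples."""
    return PlasticityParams(kappa=4.17e-3)


@pytest.fixture
def plast_net():
    """Default plasticity table (continuous leak of 0.42 % per second)."""
    return PlasticityParams()


@pytest.fixture
def neuron():
    return NeuronParams()
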