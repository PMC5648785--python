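import numpy as np
import pytest

from thalamodyn import (
    IntegrationSettings,
    StimulusSet,
    StimulusSpec,
    default_parameters,
)
from thalamodyn.params import SynapseParams


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def quiet_stimuli():
    """Constant-input operating point with no sinusoidal components."""
    return StimulusSet(
        sensory=StimulusSpec(bias=11.0),
        cortical=StimulusSpec(bias=13.5),
        reticular_bias=12.0,
    )


@pytest.fixture
def ampa_synapse():
    return SynapseParams(A=225.0, a1=180.0, a2=900.0, V_rev=0.0, syn_type="AMPA")


@pytest.fixture
def fast_settings():
    return IntegrationSettings(rtol=1e-7, atol=1e-9, sample_dt=1e-3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
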