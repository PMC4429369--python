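import numpy as np
import pytest

from nlifsim import (
    NeuronCircuitParams,
    NeuronState,
    SwitchState,
    ThresholdSwitchSpec,
    detect_spikes,
    simulate,
)


@pytest.fixture(scope="session")
def params() -> NeuronCircuitParams:
    """Reference circuit (the operating point used for coding studies)."""
    return NeuronCircuitParams()


@pytest.fixture(scope="session")
def reference_trace(params):
    """Noise-free trace at 1 uA constant drive over 30 ms."""
    return simulate(params, 1e-6, 30e-3)


@pytest.fixture(scope="session")
def reference_train(reference_trace):
    return detect_spikes(reference_trace, 30e-3)


def make_state(params, v1, v2, s1_on=False, s2_on=False, t=0.0) -> NeuronState:
    return NeuronState(
        v1=v1, v2=v2,
        s1_state=SwitchState(s1_on, params.s1),
        s2_state=SwitchState(s2_on, params.s2),
        t=t,
    )
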