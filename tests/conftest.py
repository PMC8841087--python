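import numpy as np
import pytest

from granulequant import ConditionEffect, SimulationParams, generate_neuron_stack


@pytest.fixture(scope="session")
def small_params():
    """Compact field used where full-size stacks would only cost time."""
    return SimulationParams(
        image_shape=(10, 128, 128),
        n_nuclei=1,
        n_neurites=2,
        seed=0,
    )


@pytest.fixture(scope="session")
def default_stack():
    """One full-size stack with ground truth, shared across read-only tests."""
    params = SimulationParams(seed=7)
    return generate_neuron_stack(params) + (params,)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def kd_effects():
    """Knockdown effect multipliers exercised throughout: fewer, larger,
    brighter granules (NCDN-KD style) and dimmer cytosol (FUS-KD style)."""
    return {
        "CTL-KD": ConditionEffect(),
        "NCDN-KD1": ConditionEffect(density=0.5, size=1.5, amplitude=1.3),
        "FUS-KD1": ConditionEffect(cytosol=0.7),
    }
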