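import numpy as np
import pytest

from metamem import GAConfig, TaskConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def task_cfg():
    return TaskConfig()


@pytest.fixture
def quiet_cfg():
    """Task configuration with all noise disabled (deterministic agents)."""
    return TaskConfig(sigma_input=0.0, sigma_neuron=0.0)


@pytest.fixture
def ga_cfg():
    return GAConfig()


class FixedRandom:
    """Minimal rng stub whose .random() replays a fixed sequence."""

    def __init__(self, values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)
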