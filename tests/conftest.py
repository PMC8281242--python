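import numpy as np
import pytest

from tmteeg import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def layout_a():
    return synth.generate_layout("A", 0, seed=7)


@pytest.fixture(scope="session")
def layout_b():
    return synth.generate_layout("B", 0, seed=7)


@pytest.fixture(scope="session")
def simulated_trial(layout_a):
    """One default-parameter part-A trial with its ground truth."""
    rng = np.random.default_rng(99)
    params = synth.BehaviorSimParams()
    trace, truth, sequence = synth.simulate_trial_behavior(
        layout_a, params, "A", rng, 40.0
    )
    return trace, truth, sequence
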