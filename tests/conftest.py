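import numpy as np
import pytest

from fearscope import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def habituation_schedule():
    return syn.build_schedule("habituation", seed=1)


@pytest.fixture(scope="session")
def training_schedule():
    return syn.build_schedule("training", seed=1)


@pytest.fixture(scope="session")
def recall_schedule():
    return syn.build_schedule("recall", seed=1)


@pytest.fixture(scope="session")
def small_session(training_schedule):
    """A small but complete simulated training session with ground truth."""
    behavior = syn.simulate_behavior(training_schedule, syn.BehaviorSpec(seed=2))
    pspec = syn.PopulationSpec(
        n_neurons=20,
        n_us_responders=4,
        n_cs_responders=3,
        n_movon_responders=3,
        seed=2,
    )
    traceset, truth = syn.simulate_population(training_schedule, behavior, pspec)
    return training_schedule, behavior, traceset, truth
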