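import numpy as np
import pytest

from stdpop import NeuronParams, RateTheoryInputs


@pytest.fixture(scope="session")
def neuron():
    return NeuronParams()


@pytest.fixture(scope="session")
def table1_inputs():
    """Standard input statistics: 1000 excitatory + 250 inhibitory at 10 Hz."""
    return RateTheoryInputs(0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_event_sequence(rng, n_pre=40, n_post=30, t_max=3000.0):
    """A merged random pre/post event sequence, time-sorted."""
    pre = rng.uniform(0, t_max, n_pre)
    post = rng.uniform(0, t_max, n_post)
    events = [(t, "pre") for t in pre] + [(t, "post") for t in post]
    events.sort()
    return events
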