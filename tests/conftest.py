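import numpy as np
import pytest

from semmix import examples, simulator


@pytest.fixture(scope="session")
def school_spec():
    return examples.school_model()


@pytest.fixture(scope="session")
def school_data(school_spec):
    plan = simulator.ClusterSizePlan.from_total(60, 400)
    return simulator.simulate_dataset(school_spec, 60, plan, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
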