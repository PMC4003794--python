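import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_data():
    """200 planted-rule instances (2 disjoint rules, 5% label noise) plus a
    fresh holdout draw from the same generator state chain."""
    from fuzzyswarm.boosting import WeightedDataset
    from fuzzyswarm.data_io import generate_synthetic, planted_two_rule_spec

    spec = planted_two_rule_spec()
    g = np.random.default_rng(7)
    instances, truth = generate_synthetic(spec, g)
    holdout, _ = generate_synthetic(spec, g)
    return WeightedDataset.from_instances(instances), holdout, truth


def random_rule_codes(rng, n, count):
    """Random antecedent strings as (count, n) alphabet-index arrays."""
    return rng.integers(0, 15, size=(count, n))
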