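import numpy as np
import pytest

import polyspike as ps


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noiseless_config():
    """All stochastic terms off: the pipeline must reproduce truth exactly."""
    return ps.SimulationConfig(
        loss_sigma=0.0, cq_sigma=0.0, replicate_effect_sd=0.0, seed=11
    )


@pytest.fixture
def default_config():
    return ps.SimulationConfig(seed=5)


def brute_force_fw(fractions, values):
    """Independent weighted-average oracle: plain Python loop arithmetic."""
    total = sum(v for v in values if v == v)
    pct = [100.0 * v / total for v in values]
    return sum(f * p for f, p in zip(fractions, pct)) / 100.0
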