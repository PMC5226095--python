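import numpy as np
import pytest

from dazzletrack import observer_synth, swarm_sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_variable_config():
    return swarm_sim.trial_config_for(10, "trinary", "variable", seed=3)


@pytest.fixture
def constant_config():
    return swarm_sim.trial_config_for(10, "trinary", "constant", seed=4)


def balanced_schedule(reps=1, n_levels=(1, 10, 30, 50)):
    """Fully crossed trial list without practice trials."""
    out = []
    for n in n_levels:
        for c in ("orthogonal", "parallel", "trinary"):
            for s in ("constant", "variable"):
                for _ in range(reps):
                    out.append(observer_synth.TrialSpec(n, c, s))
    return out
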