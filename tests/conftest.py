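import numpy as np
import pytest

from beliefpupil import task


@pytest.fixture(scope="session")
def mixed_session() -> task.TrialSequence:
    """A 3000-trial session spanning all three hazard conditions."""
    cfg = task.TaskConfig(
        hazard_values=(0.01, 0.30, 0.99),
        n_trials=3000,
        block_length_range=(150, 350),
        seed=3,
    )
    return task.generate_session(cfg)


@pytest.fixture(scope="session")
def extreme_session() -> task.TrialSequence:
    """A 1000-trial session pairing the low and high hazard conditions."""
    return task.generate_session(task.make_fixed_schedule(3, seed=9))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
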