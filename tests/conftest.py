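import numpy as np
import pytest

from tonecloud import dual_model, stimulus


@pytest.fixture(scope="session")
def grid():
    return stimulus.build_frequency_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_batch():
    """48 localized-change trials across sizes, reproducible."""
    return stimulus.generate_trial_batch(5, repetitions=3, include_nonlocalized=False)


@pytest.fixture(scope="session")
def dual_records(grid):
    """Dual-model responses on a 320-trial localized batch (published params)."""
    trials = stimulus.generate_trial_batch(3, repetitions=20, include_nonlocalized=False)
    return dual_model.simulate_experiment(trials, dual_model.DualParams(), grid=grid)
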