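import numpy as np
import pytest

from satddm import behavior, generate


@pytest.fixture(scope="session")
def small_experiment():
    """One generated 2-subject, 2-session experiment shared across tests."""
    design = generate.ExperimentDesign(n_subjects=2, n_sessions=2)
    truth = generate.sample_ground_truth(design, seed=77)
    trials = generate.generate_experiment(design, truth, seed=77, dt=1e-3)
    return design, truth, trials


@pytest.fixture(scope="session")
def filtered_small(small_experiment):
    _, truth, trials = small_experiment
    filtered, frac = behavior.filter_trials(trials)
    return truth, filtered, frac


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
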