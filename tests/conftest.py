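import numpy as np
import pytest

import tactile_rivalry as tr


@pytest.fixture(scope="session")
def default_params():
    return tr.GeneratorParams(seed=11)


@pytest.fixture(scope="session")
def dataset(default_params):
    """Full default synthetic experiment (15 subjects x 5 dI x 3 reps)."""
    return tr.generate_dataset(default_params)


@pytest.fixture(scope="session")
def kept_trials(dataset):
    kept, _ = tr.apply_exclusion(dataset)
    return kept


@pytest.fixture(scope="session")
def many_trials(default_params):
    """500 single-condition trials for correlation/marginal statistics."""
    rng = np.random.default_rng(123)
    return [
        tr.Trial(subject=0, delta_i=2.0, repetition=i,
                 phases=tr.sample_phase_sequence(default_params, 2.0, 1.0,
                                                 180.0, rng))
        for i in range(500)
    ]


@pytest.fixture
def simple_phases():
    return [
        tr.PerceptPhase(tr.SIM, 0.0, 10.0),
        tr.PerceptPhase(tr.AM, 10.0, 20.0),
        tr.PerceptPhase(tr.SIM, 30.0, 30.0),
    ]
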