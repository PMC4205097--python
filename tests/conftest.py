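import numpy as np
import pytest

from oscimp import SimConfig, pipeline, synthetic


@pytest.fixture(scope="session")
def small_session():
    """One rat, 5-minute session, all regions — shared read-only fixture."""
    cfg = SimConfig(n_rats=1, session_duration=300.0, seed=101)
    return synthetic.simulate_session(cfg, 0)


@pytest.fixture(scope="session")
def small_cohort():
    """Three rats, 7-minute sessions, moderate modulation depth."""
    cfg = SimConfig(n_rats=3, session_duration=420.0, seed=202)
    return synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_gamma_tensors(small_cohort):
    """Wait-start and nose-poke gamma60 tensors for the shared cohort."""
    return pipeline.cohort_tensors(small_cohort, measures=("gamma60",))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
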