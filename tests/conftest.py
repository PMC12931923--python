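import numpy as np
import pytest

from locus.models import ObservationSet, model_by_id
from locus.selection import simulate_subject
from locus.task import generate_session


@pytest.fixture(scope="session")
def session_160():
    return generate_session(seed=7, n_trials=160)


@pytest.fixture(scope="session")
def model2_dataset() -> ObservationSet:
    """Moderate dataset simulated from the dual model at known parameters."""
    spec = model_by_id(2)
    kappa = np.array([0.2, -0.3, 0.1, -0.4])
    return simulate_subject(spec, kappa, seed=11, n_trials=200)


@pytest.fixture(scope="session")
def model7_dataset() -> ObservationSet:
    spec = model_by_id(7)
    rng = np.random.default_rng(5)
    kappa = rng.normal(0.0, np.sqrt(1 / 8), spec.n_params)
    return simulate_subject(spec, kappa, seed=13, n_trials=200)
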