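import numpy as np
import pytest

import mtmdecode as md


@pytest.fixture(scope="session")
def geometry():
    return md.TaskGeometry()


@pytest.fixture(scope="session")
def benchmark_session():
    """Default synthetic benchmark: 240 trials, 40 units, start=bottom, seed 0."""
    return md.generate_benchmark_session(seed=0)


@pytest.fixture(scope="session")
def benchmark_model_set(benchmark_session):
    return md.fit_model_set(benchmark_session)


@pytest.fixture(scope="session")
def small_session():
    """A cheaper session for LOOCV-heavy tests: 60 trials, 12 units."""
    return md.generate_benchmark_session(seed=7, n_trials=60, n_units=12)
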