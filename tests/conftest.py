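import numpy as np
import pytest

from frailcurve import SimulationParams, add_fi_columns, generate_cohort


@pytest.fixture(scope="session")
def scored_cohort():
    """A mid-sized default cohort with FI columns, shared across tests."""
    params = SimulationParams(n_participants=6000, seed=3)
    df, _ = generate_cohort(params)
    return add_fi_columns(df)


@pytest.fixture(scope="session")
def large_cohort():
    """A large default cohort for asymptotic checks."""
    params = SimulationParams(n_participants=20000, seed=11)
    df, truth = generate_cohort(params)
    return add_fi_columns(df), truth
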