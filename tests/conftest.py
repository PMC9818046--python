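import numpy as np
import pytest

from tremorlab.synth import CohortGenSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_cohort():
    """Small pure-direct-effect cohort (22 control / 20 ET)."""
    table, truth = generate_cohort(CohortGenSpec(seed=0))
    return table, truth


@pytest.fixture(scope="session")
def mediated_cohort():
    """Large cohort with a real mediated path: T->M = 2, M->Y = 1.5."""
    spec = CohortGenSpec(n_control=1000, n_et=1000, t_to_m=2.0, m_to_y=1.5,
                         t_to_y=5.0, seed=42)
    table, truth = generate_cohort(spec)
    return table, truth
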