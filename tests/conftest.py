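import numpy as np
import pytest

from stabflex.landscape import FPGrid, fp_steady_state
from stabflex.params import reference_subject
from stabflex.rule import RuleParams, compute_effective_couplings
from stabflex.stats import summarize
from stabflex.task import simulate_session


@pytest.fixture(scope="session")
def standard_couplings():
    """Effective couplings at standard scaling (s_NMDA = s_GABA = 1)."""
    return compute_effective_couplings(RuleParams())


@pytest.fixture(scope="session")
def ref_params():
    return reference_subject()


@pytest.fixture(scope="session")
def ref_session(ref_params):
    """One synthetic 300-trial session at the reference parameters."""
    return simulate_session(ref_params, rng_seed=11)


@pytest.fixture(scope="session")
def ref_summary(ref_session):
    return summarize(ref_session)


@pytest.fixture(scope="session")
def standard_landscape_64():
    """Steady-state landscape at standard parameters on a 64-grid."""
    return fp_steady_state(RuleParams(sigma_rule=0.1), FPGrid(64))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
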