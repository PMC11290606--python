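import pytest

from genmix.cohort import CohortSpec, simulate_cohort
from genmix.designs import build_exp2_design, exp2_stimuli


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-per-group differential-conditioning cohort with ground truth."""
    spec = CohortSpec(n_per_group=(2, 2, 2, 2), seed=21)
    table, truth = simulate_cohort(spec)
    return table, truth


@pytest.fixture(scope="session")
def exp2_design():
    return build_exp2_design()


@pytest.fixture(scope="session")
def exp2_grid():
    return exp2_stimuli()
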