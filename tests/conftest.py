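import pytest

from tp53axis import (
    cohort_from_marginal_counts,
    preset,
    simulate_cohort,
)
from tp53axis.synthetic_cohort import AGE_GE60_COUNTS, SEX_COUNTS


@pytest.fixture(scope="session")
def replica_cohort():
    """One cohort drawn under the full study-replica generative model."""
    return simulate_cohort(preset("study_replica", seed=1))


@pytest.fixture(scope="session")
def null_cohort():
    """One cohort with no genetic or covariate effects."""
    return simulate_cohort(preset("null", seed=2))


@pytest.fixture(scope="session")
def printed_counts_cohort():
    """Deterministic cohort whose marginal genotype counts, sex and
    age-group composition equal the published study tables."""
    return cohort_from_marginal_counts(sex_counts=SEX_COUNTS,
                                       age_ge60_counts=AGE_GE60_COUNTS)
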