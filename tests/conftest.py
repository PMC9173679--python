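import pytest

from myotriage.simulate import default_params, sample_cohort


@pytest.fixture(scope="session")
def cohort_10k():
    """Default-condition synthetic cohort, 10^4 patients."""
    return sample_cohort(default_params(n=10_000, seed=0))


@pytest.fixture(scope="session")
def cohort_100k():
    """Large cohort for distribution-recovery checks."""
    return sample_cohort(default_params(n=100_000, seed=0))


@pytest.fixture(scope="session")
def cohort_small():
    """500-patient cohort for derivation-search tests."""
    return sample_cohort(default_params(n=500, seed=11))
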