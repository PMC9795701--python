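import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_truth():
    """A minimal cohort used by fast unit/integration tests."""
    from straintrace import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_families=1,
        individuals_per_family=2,
        visits_per_individual=1,
        taxa=[("Prevotella", 1, 2000, 1.0, 1.0), ("Streptococcus", 1, 2000, 1.0, 1.0)],
        variants_per_taxon=4,
        transmission_prob=0.5,
        base_error_rate=0.0,
        coverage_dna=20.0,
        coverage_rna=15.0,
        peptide_depth=400.0,
        seed=42,
    )
    return generate_cohort(cfg)
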