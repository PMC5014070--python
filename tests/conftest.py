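import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# The two-symbol illustration sequence: compressing it saves 7 of 19
# symbols ({1,2,1} first, then one of two tied 4-grams).
WORKED_EXAMPLE = [1, 2, 1, 1, 2, 1, 2, 2, 1, 2, 1, 1, 2, 1, 2, 2, 1, 2, 1]


@pytest.fixture
def worked_example():
    return list(WORKED_EXAMPLE)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_cohort():
    """Two-condition cohort with one motif enriched in condition A."""
    from cgram import CohortSpec, PlantedMotif, generate_cohort

    spec = CohortSpec(
        conditions=("A", "B"),
        n_per_condition=10,
        sequence_length=800,
        alphabet_size=90,
        planted_motifs=(PlantedMotif((7, 3, 9, 3), {"A": 0.02, "B": 0.0}),),
        seed=424242,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_cohort_compressed(planted_cohort):
    from cgram import compress

    return [compress(s) for s in planted_cohort.sequences]
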