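import numpy as np
import pytest

from softgleason.ontology import default_ontology
from softgleason.synthetic import (
    SyntheticCohortSpec,
    generate_cohort_data,
    cohort_items,
    identity_profile,
)


@pytest.fixture(scope="session")
def ontology():
    return default_ontology()


@pytest.fixture(scope="session")
def small_cohort():
    """Eight mildly noisy synthetic cores with three annotators."""
    spec = SyntheticCohortSpec(n_images=8, seed=11)
    onto = default_ontology()
    return generate_cohort_data(spec, onto)


@pytest.fixture(scope="session")
def small_items(small_cohort):
    items, truths = cohort_items(small_cohort, level="explanation")
    return items, truths


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: three identical annotators reproduce ground truth."""
    spec = SyntheticCohortSpec(
        n_images=4,
        seed=5,
        profiles=[identity_profile(3) for _ in range(3)],
    )
    return generate_cohort_data(spec, default_ontology())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
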