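import numpy as np
import pytest

from falffpipe.synth import SyntheticCohortSpec, cohort_masks, generate_cohort


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticCohortSpec:
    """Small cohort for pipeline-level tests: 3+3 subjects, 64 volumes."""
    return SyntheticCohortSpec(n_low=3, n_high=3, n_volumes=64, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    cohort, runs = generate_cohort(tiny_spec)
    return tiny_spec, cohort, runs


@pytest.fixture(scope="session")
def tiny_masks(tiny_spec):
    return cohort_masks(tiny_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
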