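import numpy as np
import pytest

from gmconnsurv.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A desk-scale cohort: 12 regions on a small lattice, 3 factors."""
    return CohortSpec(
        n_subjects=120,
        volume_shape=(18, 18, 18),
        n_regions=12,
        latent_dim=3,
        beta_true=np.array([0.8, -0.8, 0.5]),
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
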