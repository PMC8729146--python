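import numpy as np
import pytest

from toastnet import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """A fast, clearly separable cohort for pipeline tests."""
    return CohortSpec(
        n_patients=400,
        class_counts=(200, 40, 80, 30, 50),
        n_features=20,
        n_informative=8,
        effect_size=1.5,
        missing_rate=0.01,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_proba(rng, n, k=5):
    """Random row-normalized probability matrix."""
    raw = rng.random((n, k)) + 1e-3
    return raw / raw.sum(axis=1, keepdims=True)
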