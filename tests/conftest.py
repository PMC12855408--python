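import numpy as np
import pytest

import triboostcardio as tb


@pytest.fixture(scope="session")
def small_cohort():
    """300-sample cohort, 3 informative of 8 features."""
    spec = tb.CohortSpec(n_samples=300, n_informative=3, n_noise=5,
                         effect_sizes=(2.0, 2.0, 2.0), seed=42)
    return tb.generate_cohort(spec)


@pytest.fixture(scope="session")
def medium_cohort():
    """2000-sample cohort, 4 informative of 20 features."""
    spec = tb.CohortSpec(n_samples=2000, seed=1)
    return tb.generate_cohort(spec)


@pytest.fixture(scope="session")
def separable_data():
    """Feature 0 perfectly separates the classes; others are noise."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(80, 5))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y == 1, 1.0, -1.0)  # widen the margin
    return X, y
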