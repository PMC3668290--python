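import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20130425)


@pytest.fixture
def small_dataset(rng):
    """80 individuals x 5 SNPs with a planted checkerboard signal."""
    from mbmdr_robust import GenotypeMatrix, m170_high_indicator

    values = rng.integers(0, 3, size=(80, 5))
    t = rng.normal(size=80) + 2.0 * m170_high_indicator(values[:, 0], values[:, 1])
    return GenotypeMatrix(values), t
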