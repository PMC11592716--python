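import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patches(rng):
    """50 random single-slice 4x4 patches with a handful of gray levels."""
    return [rng.integers(0, 120, size=(4, 4, 1)).astype(float) for _ in range(50)]


@pytest.fixture
def tiny_cohort_config():
    """Small phantom cohort for pipeline tests: 9 cases, small volumes."""
    from radiomaps.synthetic import CohortConfig

    return CohortConfig(
        n_noPCa_PZ=3,
        n_noPCa_TZ=1,
        n_ciPCa_PZ=1,
        n_ciPCa_TZ=1,
        n_csPCa_PZ=2,
        n_csPCa_TZ=1,
        image_shape=(32, 32, 4),
        seed=11,
    )
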