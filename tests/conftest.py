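import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from modcoupling import SyntheticConfig, generate_cohort

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def small_config(**overrides) -> SyntheticConfig:
    """A 12-region, 3-module cohort small enough for fast unit tests."""
    defaults = dict(
        n_patients=4,
        n_controls=5,
        n_regions=12,
        n_timepoints=64,
        module_sizes=(4, 4, 4),
        effect_map={},
        motion_outlier_patients=0,
        motion_outlier_controls=0,
        crlb_outlier_patients=0,
        seed=7,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """The default stated-world cohort at seed 42 (shared, read-only)."""
    return generate_cohort(SyntheticConfig(seed=42))


@pytest.fixture
def tiny_cohort():
    return generate_cohort(small_config())
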