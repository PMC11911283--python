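import numpy as np
import pytest

from parkmlr import (
    SyntheticCohortSpec,
    augment_with_ud,
    build_mask,
    fit_ssm,
    grid_search,
    simulate_cohort,
    stack,
)


@pytest.fixture(scope="session")
def small_spec():
    """A fast 16^3 cohort spec used across module tests."""
    return SyntheticCohortSpec(
        grid_shape=(16, 16, 16),
        n_per_group=6,
        pattern_amplitude=0.15,
        noise_sd=0.05,
        gsf_range=(0.8, 1.2),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_ssm(small_cohort):
    """SSM/PCA state of the UD-augmented small cohort at a 25% mask."""
    augmented, plan = augment_with_ud(small_cohort.images, seed=11)
    mask = build_mask(augmented, 25)
    model = fit_ssm(stack(augmented, mask))
    return model


@pytest.fixture(scope="session")
def small_selection(small_cohort):
    """Full AIC grid search on the small cohort (thresholds pruned for speed)."""
    return grid_search(small_cohort.images, thresholds=(20, 25, 30), seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
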