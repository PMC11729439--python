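import pytest

from mggf import (AugmentSpec, CohortSpec, PanelSpec, augment,
                  generate_cohort, split_train_test, standardize)

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def panel_spec():
    return PanelSpec.default()


@pytest.fixture(scope="session")
def cohort(panel_spec):
    """The default 118-patient synthetic cohort (fixed fixture seed)."""
    return generate_cohort(CohortSpec(seed=FIXTURE_SEED), panel_spec)


@pytest.fixture(scope="session")
def augmented(cohort, panel_spec):
    """Standardized cohort plus two noisy copies, subsampled to 216 rows."""
    std, _ = standardize(cohort, panel_spec)
    return augment(std, AugmentSpec(seed=FIXTURE_SEED + 1), panel_spec)


@pytest.fixture(scope="session")
def split(augmented):
    """Source-grouped 4:1 train/test split of the augmented table."""
    return split_train_test(augmented, 0.2, seed=FIXTURE_SEED + 2,
                            by_source=True)
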