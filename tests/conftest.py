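import numpy as np
import pytest

from hotspotnac.cohort import CohortSpec, MisalignmentTransform, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-patient cohort at full region size, default rates and misalignment."""
    spec = CohortSpec(n_patients=10, n_pcr=6, n_rd=4, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def aligned_cohort():
    """A small cohort with identity transform and no jitter: IHC points
    coincide exactly with their flagged tumor cells."""
    spec = CohortSpec(n_patients=4, n_pcr=2, n_rd=2, region_size_px=4000, seed=11)
    return generate_cohort(spec, transform=MisalignmentTransform.identity())


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
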