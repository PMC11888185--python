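import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from toibn.cohort import CohortSpec, make_cohort  # noqa: E402


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast cohort: small grid, few subjects, short scans."""
    return CohortSpec(
        grid_shape=(12, 12, 6),
        n_subjects_per_group=3,
        T=40,
        K=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return make_cohort(tiny_spec)


@pytest.fixture
def full_mask_grid():
    from toibn.volumes import VolumeGrid

    def make(data):
        data = np.asarray(data, dtype=float)
        return VolumeGrid(data, np.ones(data.shape, dtype=bool))

    return make
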