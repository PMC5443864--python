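"""Shared fixtures: tiny masks and desk-scale synthetic cohorts.

Cohorts are session-scoped so expensive generation/fitting is shared; all
randomness is seeded so the suite is fully deterministic.
"""

import numpy as np
import pytest

from mvbc.data_model import BrainMask
from mvbc.synthetic import (
    complementary_config,
    generate_cohort,
    null_config,
    strong_config,
)

SMALL_SHAPE = (12, 12, 12)
N_PER_CLASS = 15


def box_mask(*shape):
    return BrainMask.from_volume(np.ones(shape, dtype=bool), np.eye(4))


@pytest.fixture(scope="session")
def chain_mask():
    """1x1x4 chain of voxels."""
    return box_mask(1, 1, 4)


@pytest.fixture(scope="session")
def strong_cohort():
    return generate_cohort(
        strong_config(seed=0, shape=SMALL_SHAPE, n_per_class=N_PER_CLASS)
    )


@pytest.fixture(scope="session")
def null_cohort():
    import warnings

    with warnings.catch_warnings():
        # zero effect amplitudes are the point of this cohort
        warnings.simplefilter("ignore", UserWarning)
        return generate_cohort(
            null_config(seed=0, shape=SMALL_SHAPE, n_per_class=N_PER_CLASS)
        )


@pytest.fixture(scope="session")
def complementary_cohort():
    return generate_cohort(
        complementary_config(seed=0, shape=SMALL_SHAPE, n_per_class=N_PER_CLASS)
    )
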