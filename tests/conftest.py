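import numpy as np
import pytest

from intpipe import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny planted-effect cohort shared by read-only tests."""
    spec = synth.CohortSpec(
        n_per_group=4,
        grid_shape=(8, 8, 8),
        tr=2.0,
        n_frames=80,
        seed=101,
        planted_regions=[
            synth.box_region((8, 8, 8), (2, 2, 2), (2, 2, 2), "planted", 0.6, 0.2)
        ],
    )
    return synth.simulate_cohort(spec)
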