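import numpy as np
import pytest

import zmapsim as z


@pytest.fixture(scope="session")
def small_config():
    """Two tasks, three contrasts, tiny grid — fast unit-test cohort."""
    return z.CohortConfig(
        n_subjects=12,
        n_families=6,
        n_tasks=2,
        contrasts_per_task=(2, 1),
        grid_shape=(14, 14, 14),
        group_size=4,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    specs = z.build_contrast_specs(small_config)
    records = z.make_subject_records(small_config)
    maps = z.simulate_subject_maps(specs, records, small_config)
    mask = z.BrainMask(z.ellipsoid_mask(small_config.grid_shape))
    return small_config, specs, records, maps, mask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
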