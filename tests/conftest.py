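import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fivmap.parcellation import RelevanceTable
from fivmap.synthetic import CohortConfig, generate_parcellation

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")

#: coarse grid used throughout the tests: keeps lesion growth and
#: segmentation fast while leaving ~400 mL per hemisphere to grow into.
TEST_GRID = {"grid_shape": (32, 32, 32), "voxel_spacing": (4.0, 4.0, 4.0)}


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_patients=40, seed=123, **TEST_GRID)


@pytest.fixture(scope="session")
def parc(small_config):
    return generate_parcellation(small_config)


@pytest.fixture(scope="session")
def relevance_table(parc) -> RelevanceTable:
    return RelevanceTable.from_parcellation(parc)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
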