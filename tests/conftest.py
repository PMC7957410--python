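import numpy as np
import pytest

from circaburst import StudyDesign, default_params, simulate_dataset


@pytest.fixture(scope="session")
def small_design():
    """Reduced study design used throughout the unit tests: same 7 time
    points and 3 replicates as the full design, fewer cells."""
    return StudyDesign(cells_per_timepoint=60)


@pytest.fixture(scope="session")
def pair_params():
    return default_params(("Nr1d1", "Cry1"))


@pytest.fixture(scope="session")
def m4_table(small_design, pair_params):
    return simulate_dataset("M4", pair_params, small_design, seed=101)


@pytest.fixture(scope="session")
def m1_table(small_design, pair_params):
    return simulate_dataset("M1", pair_params, small_design, seed=102)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
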