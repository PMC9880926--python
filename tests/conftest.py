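import warnings

import numpy as np
import pytest

import relapsekit as rk
from relapsekit.cohort import DEFAULT_STREAM_SPECS, StreamSpec

warnings.filterwarnings("ignore", message="quasi-separation")


@pytest.fixture(scope="session")
def small_config() -> rk.CohortConfig:
    """A scaled-down three-site cohort used across integration tests."""
    return rk.CohortConfig(
        site_specs={
            "Boston": {"R": 2, "NR": 3, "C": 2},
            "Bangalore": {"R": 2, "NR": 3, "C": 4},
            "Bhopal": {"R": 1, "NR": 4, "C": 4},
        },
        enrollment_mean_days=90,
        enrollment_sd_days=20,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return rk.generate_cohort(small_config, seed=7)


@pytest.fixture(scope="session")
def small_matrices(small_cohort):
    return rk.simulate_cohort_features(small_cohort)


@pytest.fixture(scope="session")
def iid_config() -> rk.CohortConfig:
    """Scaled cohort with independent (phi = 0) streams — the conditions
    under which the analytic enrichment oracle is exact."""
    specs = {k: StreamSpec(v.mean, v.sd, 0.0) for k, v in DEFAULT_STREAM_SPECS.items()}
    return rk.CohortConfig(
        site_specs={
            "Boston": {"R": 5, "NR": 8, "C": 4},
            "Bangalore": {"R": 4, "NR": 8, "C": 12},
            "Bhopal": {"R": 2, "NR": 11, "C": 12},
        },
        enrollment_mean_days=120,
        enrollment_sd_days=40,
        stream_specs=specs,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
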