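import numpy as np
import pytest

from catfda.grid import DEFAULT_GRID
from catfda.preprocessing import profile_from_series
from catfda.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort shared across tests (6 Normal + 8 DJD cats)."""
    config = GeneratorConfig(seed=1234, n_per_group=(("Normal", 6), ("DJD", 8)))
    series, covariates, truth = generate_cohort(config)
    return config, series, covariates, truth


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    """Per-subject profiles built from the shared small cohort."""
    _, series, covariates, _ = small_cohort
    by_cat = {}
    for s in series:
        by_cat.setdefault(s.cat_id, []).append(s)
    profiles = {cid: profile_from_series(days) for cid, days in sorted(by_cat.items())}
    groups = dict(zip(covariates["cat_id"], covariates["group"]))
    return profiles, groups


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
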