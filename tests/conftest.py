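import numpy as np
import pytest

from netclass.cohort import CohortSpec, DEFAULT_COVARIATES


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def tiny_spec(**overrides) -> CohortSpec:
    """Small two-group spec used across tests; overridable per test."""
    base = dict(
        group_names=("HC", "bvFTD"),
        group_sizes=(12, 12),
        n_roi=8,
        grid_dims=(6, 6, 6),
        n_timepoints=60,
        n_tracts=10,
        seed=7,
    )
    base.update(overrides)
    return CohortSpec(**base)


def null_covariates(groups):
    """Identical covariate plans for every group (no covariate signal)."""
    return {g: DEFAULT_COVARIATES["HC"] for g in groups}


@pytest.fixture
def two_group_spec():
    return tiny_spec()
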