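import warnings

import numpy as np
import pytest

from plasmaclust import (
    CohortConfig,
    Hyperparams,
    build_kernel_bank,
    embed_and_cluster,
    fit_cimlr,
    generate_cohort,
    minmax_scale,
)


@pytest.fixture(scope="session")
def small_cohort():
    """90 subjects, 24 markers (6 informative), 3 planted clusters."""
    cfg = CohortConfig(
        n_subjects=90,
        n_markers=24,
        n_informative=6,
        n_clusters=3,
        cluster_proportions=(1 / 3, 1 / 3, 1 / 3),
        n_regions=10,
        n_interaction_regions=4,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_scaled(small_cohort):
    return minmax_scale(small_cohort.marker_matrix)


@pytest.fixture(scope="session")
def small_bank(small_scaled):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_kernel_bank(small_scaled)


@pytest.fixture(scope="session")
def small_model(small_bank):
    model = fit_cimlr(small_bank, Hyperparams(n_clusters=3))
    return embed_and_cluster(model, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
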