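import pytest

from genecol import (
    generate_design,
    generate_origins,
    impute,
    normalize,
    pool_across_chambers,
    population_chamber_means,
    simulate_observations,
)
from genecol.synthetic import CLIMATE_VARS


@pytest.fixture(scope="session")
def small_trial():
    """A modest synthetic trial shared by the downstream-stage tests:
    60 seedlots in 3 well-separated groups, 2 chambers x 4 blocks x 40."""
    origins, truth = generate_origins(60, 3, seed=11, separation=2.0)
    layout = generate_design(origins, n_chambers=2, blocks_per_chamber=4, block_size=40, seed=12)
    obs = simulate_observations(layout, origins, truth, seed=13)
    return origins, truth, layout, obs


@pytest.fixture(scope="session")
def pooled_matrix(small_trial):
    _, _, _, obs = small_trial
    return pool_across_chambers(impute(normalize(population_chamber_means(obs))))


@pytest.fixture(scope="session")
def climate_predictors(small_trial, pooled_matrix):
    origins, *_ = small_trial
    return origins.set_index("seedlot_id")[CLIMATE_VARS].reindex(pooled_matrix.values.index)
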