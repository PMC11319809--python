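import pytest

import borealec as bc

# small domains keep the default suite fast; the generator invariants do not
# depend on domain size
SMALL_GRID = dict(n_lat=7, n_lon=6, lat_bounds=(50.0, 78.0), lon_bounds=(0.0, 30.0))


@pytest.fixture(scope="session")
def small_grid():
    return bc.GridSpec(**SMALL_GRID)


@pytest.fixture(scope="session")
def noisefree_config(small_grid):
    return bc.EnsembleConfig.default(
        n_models=3, seed=11, noise_cv=0.0, grid=small_grid
    )


@pytest.fixture(scope="session")
def noisefree_pair(noisefree_config):
    return bc.generate_model(noisefree_config, 0)


@pytest.fixture(scope="session")
def noisefree_analysis(noisefree_pair):
    s1, s2 = noisefree_pair
    return bc.analyze_pair(s1, s2)


@pytest.fixture(scope="session")
def noisefree_ensemble():
    """8-model noise-free ensemble analysis on the default study domain."""
    config = bc.EnsembleConfig.default(n_models=8, seed=3, noise_cv=0.0)
    return config, bc.run_ensemble_analysis(config=config)
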