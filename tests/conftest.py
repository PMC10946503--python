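import numpy as np
import pytest

from guildshift import pipeline, predictors, synthetic, trophic


@pytest.fixture(scope="session")
def small_env():
    """15-year, 20x20 environmental stack with a moderate warming trend."""
    return synthetic.generate_env_grids(synthetic.ScenarioConfig(
        years=tuple(range(2005, 2020)), warming_rate=0.2, grid_shape=(20, 20), seed=7))


@pytest.fixture(scope="session")
def small_fields(small_env):
    return predictors.annual_predictor_fields(small_env)


@pytest.fixture(scope="session")
def species_pool():
    return synthetic.make_species_pool(9, seed=11)


@pytest.fixture(scope="session")
def stomach_table(species_pool):
    st = synthetic.generate_stomachs(species_pool, 25, seed=5)
    return trophic.impute_masses(st, synthetic.default_length_mass_params(species_pool),
                                 synthetic.NONFISH_MASS_LOOKUP)


@pytest.fixture(scope="session")
def survey(species_pool, small_env):
    hauls, obs = synthetic.generate_survey(species_pool, small_env, n_hauls=900, seed=3)
    return hauls, obs


@pytest.fixture(scope="session")
def micro_config():
    """Smallest end-to-end configuration that still fits several models."""
    return pipeline.RunConfig(
        seed=5, n_species=6, grid_shape=(18, 18), n_hauls=900,
        survey_years=tuple(range(2006, 2020)),
        projection_years=(2020, 2035, 2050, 2065, 2080, 2095),
        scenarios=(("moderate", 0.3), ("high", 0.55)),
        n_stomachs_per_class=20, n_folds=4, min_presences=25)


@pytest.fixture(scope="session")
def micro_run(micro_config):
    """One shared end-to-end pipeline run (kept small for test runtime)."""
    return pipeline.run_pipeline(micro_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
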