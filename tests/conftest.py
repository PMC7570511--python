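import functools

import pytest

from mrbvi import SeasonConfig, compute_observations, generate_season


@functools.lru_cache(maxsize=32)
def _season_and_observations(seed: int, **overrides):
    season = generate_season(SeasonConfig(seed=seed, **overrides))
    obs = compute_observations(season.mosaics, season.rois, season.spad_table)
    return season, obs


@pytest.fixture(scope="session")
def season_cache():
    """Memoized (season, observations) per seed, shared across test modules."""
    return _season_and_observations


@pytest.fixture(scope="session")
def default_season(season_cache):
    return season_cache(1)[0]


@pytest.fixture(scope="session")
def default_observations(season_cache):
    return season_cache(1)[1]


@pytest.fixture(scope="session")
def small_season():
    """A fast 5-date, 6-plot season for structural tests."""
    cfg = SeasonConfig(n_dates=5, n_plots=6, plot_px=(30, 40), gutter_px=5,
                      grid_cols=3, canopy_midpoint=1.0, seed=7)
    return generate_season(cfg)
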