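import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phenogrid as pg
from phenogrid.models import model_year_inputs
from phenogrid.pipeline import gridded_station_temperatures

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synth_noisy():
    """Default synthetic world: 24x24 grid, SW truth, day-to-day weather."""
    return pg.generate(pg.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def synth_nf_sw():
    return pg.generate(pg.SynthConfig(seed=2).noise_free())


@pytest.fixture(scope="session")
def synth_nf_pc():
    cfg = dataclasses.replace(pg.SynthConfig(seed=2), model="pc").noise_free()
    return pg.generate(cfg)


@pytest.fixture(scope="session")
def obs_stacks(synth_noisy):
    """Station-derived gridded daily temperatures for the observed years."""
    cfg = synth_noisy.cfg
    return gridded_station_temperatures(
        synth_noisy.stations, synth_noisy.dem, cfg.observed_years
    )


def calib_inputs(data, stacks, prior_autumn):
    cfg = data.cfg
    years = range(cfg.calib_years[0], cfg.calib_years[1] + 1)
    return model_year_inputs(stacks, years, prior_autumn, cfg.chill_start)


@pytest.fixture(scope="session")
def small_geom():
    return pg.GridGeometry(nrows=4, ncols=4, lat0=43.0, lon0=140.0, res=900.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
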