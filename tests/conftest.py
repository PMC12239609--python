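import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from prnftp import CardinalTemps, Environment, WeatherSeries

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

LINEAR = CardinalTemps(8, 30, 43, kind="linear")
BETA = CardinalTemps(8, 30, 43, kind="beta")


def make_weather(tmean, start=dt.date(2015, 4, 1), n_days=None, name=None):
    """Weather series with a given mean-temperature pattern.

    ``tmean`` may be a scalar (constant series of ``n_days``) or a sequence.
    """
    if np.isscalar(tmean):
        tmean = np.full(n_days, float(tmean))
    tmean = np.asarray(tmean, dtype=float)
    idx = pd.date_range(start, periods=len(tmean), freq="D")
    return WeatherSeries(
        pd.DataFrame({"tmin": tmean - 5, "tmax": tmean + 5, "tmean": tmean}, index=idx),
        name=name,
    )


def make_env(
    env_id="E1",
    latitude=45.0,
    tmean=18.0,
    sowing=dt.date(2015, 4, 10),
    n_days=300,
    start=dt.date(2015, 4, 1),
    emergence=None,
):
    return Environment(
        env_id=env_id,
        latitude=latitude,
        longitude=0.0,
        sowing_date=sowing,
        emergence_date=emergence,
        weather=make_weather(tmean, start=start, n_days=n_days, name=env_id),
    )


@pytest.fixture
def linear_cardinals():
    return LINEAR


@pytest.fixture
def beta_cardinals():
    return BETA


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
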