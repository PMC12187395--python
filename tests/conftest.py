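import datetime as dt

import pandas as pd
import pytest

from aeroecho.synthetic_radar import SimulationConfig, SiteMetadata, generate_campaign


def small_campaign_config(seed: int = 11, days: int = 24) -> SimulationConfig:
    """A spring deployment long enough for ~50 diel periods."""
    start = dt.date(2021, 4, 1)
    sites = [SiteMetadata("hula", 33.1, 35.6, 70.0, start, start + dt.timedelta(days=days))]
    return SimulationConfig(seed=seed, sites=sites)


@pytest.fixture(scope="session")
def spring_campaign():
    """Echo/weather/truth triple for a ~25-day spring campaign."""
    return generate_campaign(small_campaign_config())


@pytest.fixture(scope="session")
def dense_campaign():
    """High-rate, mildly dispersed campaign for estimator-consistency checks
    (≥ 200 echoes in essentially every diel period)."""
    start = dt.date(2021, 4, 1)
    sites = [SiteMetadata("hula", 33.1, 35.6, 70.0, start, start + dt.timedelta(days=24))]
    cfg = SimulationConfig(
        seed=17, sites=sites, base_rate_day=320.0, base_rate_night=350.0,
        overdispersion=8.0,
    )
    return generate_campaign(cfg)


@pytest.fixture(scope="session")
def spring_sites_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [{"site_id": "hula", "latitude": 33.1, "longitude": 35.6, "elevation": 70.0}]
    )
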