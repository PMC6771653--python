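import datetime

import pytest

from cropwater.meteorology import SiteInfo
from cropwater.soil import SoilComposition, pedotransfer
from cropwater.synthetic_weather import climate_preset, generate_weather


@pytest.fixture(scope="session")
def site():
    return SiteInfo(latitude=45.0, elevation=100.0)


@pytest.fixture(scope="session")
def loam_soil():
    return pedotransfer(SoilComposition(sand_frac=0.40, clay_frac=0.22, om_frac=0.02))


@pytest.fixture(scope="session")
def temperate_year():
    spec = climate_preset("temperate", seed=42)
    return generate_weather(spec, datetime.date(2015, 1, 1), 365)


@pytest.fixture(scope="session")
def arid_year():
    spec = climate_preset("arid", seed=7)
    return generate_weather(spec, datetime.date(2015, 1, 1), 365)
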