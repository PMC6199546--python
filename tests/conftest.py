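import numpy as np
import pandas as pd
import pytest

from greencast import ClimateConfig, CropParams, SoilParams, WeatherSeries


@pytest.fixture
def climate() -> ClimateConfig:
    """Default synthetic climate with a small ensemble for speed."""
    return ClimateConfig(members_per_year={y: 10 for y in range(2000, 2030)})


@pytest.fixture
def quiet_climate() -> ClimateConfig:
    """Degenerate climate: no temperature noise, no annual cycle."""
    return ClimateConfig(
        temp_level=20.0,
        temp_amplitude=0.0,
        temp_noise_sd=0.0,
        members_per_year={2010: 5},
    )


@pytest.fixture
def toy_crop() -> CropParams:
    """Hand-steppable crop: Kcb = 1 in all stages, no soil evaporation,
    10 degree-days per toy day, maturity after three days."""
    return CropParams(
        name="toy",
        planting_doy=121,
        gdd_requirement=30.0,
        tbase=10.0,
        kcb_stages=(1.0, 1.0, 1.0, 1.0),
        stage_fractions=(0.25, 0.5, 0.75),
        ke_soil=0.0,
        wp_star=15.0,
        hi=0.5,
        root_depth=1.0,
        depletion_fraction=0.5,
    )


@pytest.fixture
def deep_soil() -> SoilParams:
    return SoilParams(fc=0.33, wp=0.13, sat=0.45, initial_fill=1.0)


def make_weather(
    n_days: int = 10,
    year: int = 2010,
    start: str = "05-01",
    tmax: float = 30.0,
    tmin: float = 10.0,
    precip: float = 0.0,
    realization: str = "OB",
    latitude: float = 45.0,
) -> WeatherSeries:
    """Constant-weather series starting 1 May (day-of-year 121)."""
    dates = pd.date_range(f"{year}-{start}", periods=n_days, freq="D")
    n = len(dates)
    return WeatherSeries(
        site_id="test",
        realization=realization,
        latitude=latitude,
        dates=dates,
        tmax=np.full(n, float(tmax)),
        tmin=np.full(n, float(tmin)),
        rhum=np.full(n, 70.0),
        wind=np.full(n, 2.0),
        srad=np.full(n, 20.0),
        precip=np.full(n, float(precip)),
    )


@pytest.fixture
def weather_factory():
    return make_weather
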