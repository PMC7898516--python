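import numpy as np
import pandas as pd
import pytest

from conipheno import synth


@pytest.fixture(scope="session")
def site_config():
    return synth.SyntheticSiteConfig(seed=1)


@pytest.fixture(scope="session")
def weather_5yr(site_config):
    return synth.generate_weather(site_config, 5)


@pytest.fixture(scope="session")
def greenness_5yr(site_config, weather_5yr):
    return synth.generate_greenness(site_config, weather_5yr)


@pytest.fixture(scope="session")
def weather_2yr():
    cfg = synth.SyntheticSiteConfig(seed=5)
    return cfg, synth.generate_weather(cfg, 2)


@pytest.fixture(scope="session")
def coupled_2yr(weather_2yr):
    """Two years of coupled greenness + half-hourly fluxes (seed 5)."""
    cfg, w = weather_2yr
    sim = synth.generate_greenness(cfg, w)
    fx = synth.generate_fluxes(cfg, sim.latent, w)
    return cfg, w, sim, fx


def triangle_series(year=2019, lo=0.35, hi=0.45, rise_start=100, peak=180, fall_end=260):
    """Analytic triangle trajectory: flat, linear rise, symmetric fall."""
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    v = np.full(doy.size, lo)
    rising = (doy >= rise_start) & (doy <= peak)
    v[rising] = lo + (hi - lo) * (doy[rising] - rise_start) / (peak - rise_start)
    falling = (doy > peak) & (doy <= fall_end)
    v[falling] = hi - (hi - lo) * (doy[falling] - peak) / (fall_end - peak)
    return pd.DataFrame({"date": dates, "value": v})
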