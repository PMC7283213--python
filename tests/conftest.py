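import numpy as np
import pandas as pd
import pytest
import xarray as xr

from sgefa import SynthConfig, make_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One canonical 20-year, 18-forcing bundle shared across tests."""
    return make_bundle(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig(seed=42)


def make_field(values, lat, lon, start="2000-01", name="field", units="K"):
    """Small gridded monthly field helper."""
    values = np.asarray(values, dtype=float)
    time = pd.period_range(start, periods=values.shape[0], freq="M").to_timestamp()
    return xr.DataArray(
        values,
        coords={"time": time, "lat": np.asarray(lat, float), "lon": np.asarray(lon, float)},
        dims=("time", "lat", "lon"),
        name=name,
        attrs={"units": units},
    )


def monthly_series(values, start="2000-01", name="x"):
    values = np.asarray(values, dtype=float)
    idx = pd.period_range(start, periods=len(values), freq="M")
    return pd.Series(values, index=idx, name=name)
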