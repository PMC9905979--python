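"""Gridded hourly weather fields and station precipitation.

Fields are stochastic but structurally faithful to a reanalysis extract:
hourly, gap-free, on an exact 0.25-degree grid, with eastward/northward
wind (m/s), temperature (K), surface pressure (Pa) and total cloud cover
(0-1), plus binary hourly rain at point stations.
"""

from __future__ import annotations

import datetime as dt  # noqa: F401  (tz handling in sampling)
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..geo import haversine_km
from .network import CAPTURE_SITES

FIELDS = ("u10", "v10", "t2m", "sp", "tcc")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _ar1(rng, n, sd, ar):
    """Stationary AR(1), mean 0, marginal s.d. ``sd``, lag-1 corr ``ar``."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(max(1.0 - ar * ar, 0.0))
    eps = rng.normal(0.0, innov_sd, size=n)
    for i in range(1, n):
        x[i] = ar * x[i - 1] + eps[i]
    return x


@dataclass
class WeatherWorld:
    """Hourly gridded fields plus station rain, with nearest-cell sampling."""

    times: np.ndarray                 # datetime64[h], ascending, gap-free
    lats: np.ndarray                  # cell-centre latitudes, ascending
    lons: np.ndarray
    fields: dict                      # name -> array (T, nlat, nlon)
    stations: pd.DataFrame            # station_id, lat, lon
    rain: np.ndarray = field(default=None)  # (T, n_stations) in {0,1}

    def _time_index(self, when) -> int:
        if hasattr(when, "tzinfo") and when.tzinfo is not None:
            when = when.astimezone(dt.timezone.utc).replace(tzinfo=None)
        when = np.datetime64(when).astype("datetime64[h]")
        i = int((when - self.times[0]) / np.timedelta64(1, "h"))
        if i < 0 or i >= len(self.times) or self.times[i] != when:
            raise ValueError(f"hour {when} outside weather coverage")
        return i

    def _cell_index(self, lat: float, lon: float):
        ilat = int(np.argmin(np.abs(self.lats - lat)))
        ilon = int(np.argmin(np.abs(self.lons - lon)))
        half = 0.5 * 0.25
        if abs(self.lats[ilat] - lat) > half + 1e-9 or abs(self.lons[ilon] - lon) > half + 1e-9:
            raise ValueError("point outside the weather grid")
        return ilat, ilon

    def sample(self, lat: float, lon: float, when) -> dict:
        """Nearest-cell, exact-hour sample of all gridded fields."""
        it = self._time_index(when)
        ilat, ilon = self._cell_index(lat, lon)
        return {name: float(self.fields[name][it, ilat, ilon]) for name in FIELDS}

    def sample_with_deltas(self, lat: float, lon: float, when) -> dict:
        """Sample plus 24-h changes (now minus 24 h earlier, same cell)."""
        now = self.sample(lat, lon, when)
        if hasattr(when, "tzinfo") and when.tzinfo is not None:
            when = when.astimezone(dt.timezone.utc).replace(tzinfo=None)
        prev_time = np.datetime64(when).astype("datetime64[h]") - np.timedelta64(24, "h")
        prev = self.sample(lat, lon, prev_time)
        now["du24"] = now["u10"] - prev["u10"]
        now["dv24"] = now["v10"] - prev["v10"]
        now["dt24"] = now["t2m"] - prev["t2m"]
        now["dp24"] = now["sp"] - prev["sp"]
        return now

    def station_rain(self, station_idx: int, when) -> int:
        return int(self.rain[self._time_index(when), station_idx])

    def nearest_station(self, lat: float, lon: float):
        """(row index, distance km) of the nearest station; ties by id."""
        d = haversine_km(
            self.stations["lat"].to_numpy(), self.stations["lon"].to_numpy(), lat, lon
        )
        order = np.lexsort((self.stations["station_id"].to_numpy(), d))
        best = int(order[0])
        return best, float(d[best])


def _station_layout(config, rng) -> pd.DataFrame:
    """Stations: one within 20 km of each capture site, rest spread around."""
    rows = []
    for i, (name, (lat, lon)) in enumerate(sorted(CAPTURE_SITES.items())):
        rows.append((f"S{i:02d}", lat + 0.05, lon - 0.05))
    lat_min, lat_max, lon_min, lon_max = config.bbox
    for j in range(len(rows), config.n_precip_stations):
        rows.append((
            f"S{j:02d}",
            float(rng.uniform(lat_min, lat_max)),
            float(rng.uniform(lon_min, lon_max)),
        ))
    return pd.DataFrame(rows, columns=["station_id", "lat", "lon"])


def simulate_weather(config) -> WeatherWorld:
    """Generate the full weather world for a simulation config.

    Temporal dynamics are shared across the grid (AR(1) wind and
    temperature, a reflected random walk for pressure, a logistic transform
    of a latent AR(1) for cloud) with static spatial offsets per cell;
    station rain is Bernoulli with probability increasing in local cloud.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    start = config.capture_date_start - dt.timedelta(days=2)
    end = config.capture_date_end + dt.timedelta(days=config.max_nights + 3)
    t0 = np.datetime64(start.isoformat(), "h")
    n_hours = int((np.datetime64(end.isoformat(), "h") - t0) / np.timedelta64(1, "h")) + 24
    times = t0 + np.arange(n_hours) * np.timedelta64(1, "h")

    lat_min, lat_max, lon_min, lon_max = config.bbox
    step = config.grid_step
    lats = np.arange(lat_min + step / 2, lat_max, step)
    lons = np.arange(lon_min + step / 2, lon_max, step)
    nlat, nlon = len(lats), len(lons)
    if nlat == 0 or nlon == 0:
        raise ValueError("bounding box too small for the grid step")

    def offsets(scale):
        return rng.normal(0.0, scale, size=(nlat, nlon))

    hours = np.arange(n_hours)
    u_t = config.u_mean + _ar1(rng, n_hours, config.u_sd, config.wind_ar)
    v_t = config.v_mean + _ar1(rng, n_hours, config.v_sd, config.wind_ar)
    diurnal = 2.0 * np.sin(2 * np.pi * (hours % 24) / 24.0)
    temp_t = config.temp_mean + diurnal + _ar1(rng, n_hours, config.temp_sd, config.temp_ar)
    # bounded random walk for pressure, reflected at the bounds
    steps = rng.normal(0.0, config.pressure_step_sd, size=n_hours)
    walk = np.cumsum(steps)
    b = config.pressure_bound
    walk = np.abs((walk + b) % (4 * b) - 2 * b) - b
    sp_t = config.pressure_mean + walk
    latent = config.cloud_bias + config.cloud_scale * _ar1(rng, n_hours, 1.0, config.cloud_ar)

    fields = {
        "u10": u_t[:, None, None] + offsets(config.spatial_sd)[None, :, :],
        "v10": v_t[:, None, None] + offsets(config.spatial_sd)[None, :, :],
        "t2m": temp_t[:, None, None] + offsets(config.spatial_sd)[None, :, :],
        "sp": sp_t[:, None, None] + offsets(config.spatial_sd * 40)[None, :, :],
        "tcc": _sigmoid(latent[:, None, None] + offsets(config.spatial_sd)[None, :, :]),
    }

    stations = _station_layout(config, rng)
    world = WeatherWorld(times=times, lats=lats, lons=lons, fields=fields,
                         stations=stations)
    # rain linked to the station's cell cloud cover
    n_st = len(stations)
    rain = np.zeros((n_hours, n_st), dtype=np.int8)
    base_logit = np.log(config.rain_base_rate / (1.0 - config.rain_base_rate))
    for j in range(n_st):
        ilat, ilon = world._cell_index(stations["lat"].iloc[j], stations["lon"].iloc[j])
        tcc = fields["tcc"][:, ilat, ilon]
        p = _sigmoid(base_logit + config.rain_cloud_slope * (tcc - 0.5))
        rain[:, j] = (rng.random(n_hours) < p).astype(np.int8)
    world.rain = rain
    return world
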