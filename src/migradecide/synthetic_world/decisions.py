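"""Ground-truth bird histories generated from the decision models.

Each bird's nightly departure is a Bernoulli draw with probability
``1 - exp(-H * exp(eta))`` where ``H`` is the configured nightly baseline
cumulative hazard and ``eta`` the standardized-covariate linear predictor;
the route is drawn from the routing logit on the eastward wind (forced
onshore for species never observed offshore), and the landing from the
landing logit on the flight-level northward-wind change and cloud cover.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..solar import sunset_utc
from .network import CAPTURE_SITES, route_length_km, route_waypoints


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class TrueBirdHistory:
    """Ground truth for one simulated bird."""

    tag_id: str
    species: str
    site: str
    capture_ts: dt.datetime
    burst_interval: float
    departure_night: int | None = None      # 1-based nights since capture
    departure_ts: dt.datetime | None = None
    route: str | None = None                # "offshore" | "onshore"
    landed: int | None = None
    flight_end_ts: dt.datetime | None = None
    waypoints: list | None = None
    censor_ts: dt.datetime | None = None    # last night observed if no flight

    def __post_init__(self):
        if self.departure_ts is not None and self.departure_ts <= self.capture_ts:
            raise ValueError("departure must be after capture")


def make_deployments(config, rng) -> list:
    """Capture schedule: (tag_id, species, site, capture_ts, burst_interval)."""
    start = config.capture_date_start
    n_days = (config.capture_date_end - start).days + 1
    lo, hi = config.burst_interval_range
    out = []
    i = 0
    sites = sorted(CAPTURE_SITES)
    for species in config.species:
        for _ in range(int(config.n_birds[species])):
            day = start + dt.timedelta(days=int(rng.integers(0, n_days)))
            capture = dt.datetime(day.year, day.month, day.day, 8, 0,
                                  tzinfo=dt.timezone.utc)
            capture += dt.timedelta(minutes=float(rng.uniform(0, 240)))
            out.append({
                "tag_id": f"tag{i:04d}",
                "species": species,
                "site": sites[i % len(sites)],
                "capture_ts": capture,
                "burst_interval": float(rng.uniform(lo, hi)),
            })
            i += 1
    return out


def _standardize(config, name, value):
    center, scale = config.standardization[name]
    return (value - center) / scale


def departure_eta(config, species, z: dict, rain: int) -> float:
    """Linear predictor of the nightly departure hazard (standardized scale)."""
    c = config.departure_coefs
    eta = (
        c["u_lin"] * z["u"] + c["u_quad"] * z["u"] ** 2
        + c["v_lin"] * z["v"] + c["v_quad"] * z["v"] ** 2
        + c["du24"] * z["du24"] + c["dv24"] * z["dv24"]
        + c["dp24"] * z["dp24"] + c["cloud"] * z["cloud"]
        + c["rain"] * rain
    )
    sp_key = f"species[{species}]"
    if sp_key in c:
        eta += c[sp_key] + c.get(f"{sp_key}:dp24", 0.0) * z["dp24"]
    return float(eta)


def offshore_probability(config, z_u: float) -> float:
    c = config.routing_coefs
    return float(_sigmoid(c["intercept"] + c["u"] * z_u))


def landing_probability(config, z_dv_flight: float, z_cloud: float) -> float:
    c = config.landing_coefs
    return float(_sigmoid(
        c["intercept"] + c["dv_flight"] * z_dv_flight + c["cloud"] * z_cloud
    ))


def simulate_decisions(world, config, deployments=None, rng=None) -> list:
    """Draw every bird's departure night, route and landing from the models."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    if deployments is None:
        deployments = make_deployments(config, rng)
    histories = []
    for dep in deployments:
        lat, lon = CAPTURE_SITES[dep["site"]]
        capture = dep["capture_ts"]
        hist = TrueBirdHistory(
            tag_id=dep["tag_id"], species=dep["species"], site=dep["site"],
            capture_ts=capture, burst_interval=dep["burst_interval"],
        )
        for night in range(1, config.max_nights + 1):
            night_date = capture.date() + dt.timedelta(days=night - 1)
            sunset = sunset_utc(lat, lon, night_date)
            w = world.sample_with_deltas(lat, lon, sunset)
            st_idx, st_dist = world.nearest_station(lat, lon)
            rain = world.station_rain(st_idx, sunset) if st_dist < 20.0 else 0
            z = {
                "u": _standardize(config, "u", w["u10"]),
                "v": _standardize(config, "v", w["v10"]),
                "du24": _standardize(config, "du24", w["du24"]),
                "dv24": _standardize(config, "dv24", w["dv24"]),
                "dp24": _standardize(config, "dp24", w["dp24"]),
                "cloud": _standardize(config, "cloud", w["tcc"]),
            }
            eta = departure_eta(config, dep["species"], z, rain)
            p_dep = 1.0 - np.exp(-config.baseline_rate * np.exp(eta))
            if rng.random() >= p_dep:
                continue
            # departed this night: route, within-night time, landing
            if dep["species"] in config.forced_onshore_species:
                route = "onshore"
            else:
                p_off = offshore_probability(config, z["u"])
                route = "offshore" if rng.random() < p_off else "onshore"
            mu, sd = (config.departure_offset_offshore if route == "offshore"
                      else config.departure_offset_onshore)
            offset_h = -1.0
            while offset_h < 0:
                offset_h = rng.normal(mu, sd)
            dep_ts = sunset + dt.timedelta(hours=float(offset_h))
            waypoints = route_waypoints(dep["site"], route)
            dist_km = route_length_km(waypoints)
            end_ts = dep_ts + dt.timedelta(seconds=dist_km * 1000.0 / config.airspeed_ms)
            end_lat, end_lon = waypoints[-1]
            w_begin = world.sample(lat, lon, _round_hour(dep_ts))
            w_end = world.sample(end_lat, end_lon, _round_hour(end_ts))
            z_dv = _standardize(config, "dv_flight", w_end["v10"] - w_begin["v10"])
            z_cl = _standardize(config, "cloud", w_end["tcc"])
            landed = int(rng.random() < landing_probability(config, z_dv, z_cl))
            hist.departure_night = night
            hist.departure_ts = dep_ts
            hist.route = route
            hist.landed = landed
            hist.flight_end_ts = end_ts
            hist.waypoints = waypoints
            break
        else:
            hist.censor_ts = capture + dt.timedelta(days=config.max_nights)
        histories.append(hist)
    return histories


def _round_hour(ts: dt.datetime) -> dt.datetime:
    ts = ts.replace(microsecond=0)
    return (ts + dt.timedelta(minutes=30)).replace(minute=0, second=0)


def truth_frame(histories) -> pd.DataFrame:
    """Ground-truth table (one row per bird) for writing to truth.csv."""
    rows = []
    for h in histories:
        rows.append({
            "tag_id": h.tag_id,
            "species": h.species,
            "site": h.site,
            "capture_ts": h.capture_ts.isoformat(),
            "departure_night": h.departure_night if h.departure_night else "",
            "departure_ts": h.departure_ts.isoformat() if h.departure_ts else "",
            "route": h.route or "",
            "landed": "" if h.landed is None else h.landed,
            "flight_end_ts": h.flight_end_ts.isoformat() if h.flight_end_ts else "",
        })
    return pd.DataFrame(rows)
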