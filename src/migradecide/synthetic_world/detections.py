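"""Noisy detection tables from ground-truth histories.

Birds emit coded bursts at their tag's fixed interval.  In flight, every
``burst_stride``-th burst is position-checked against all receivers and
detected with ``detection_prob`` when within the detection radius.  At
stopover (and after a landing) birds emit short daily/hourly beacon
clusters at their local receiver.  False positives are Poisson per
receiver-hour with tag IDs drawn from the deployed-tag list.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from ..geo import great_circle_waypoint, haversine_km
from .network import CAPTURE_SITES, route_length_km

COLUMNS = ["tag_id", "timestamp", "receiver_id"]


def _route_positions(waypoints, d_km):
    """Positions at cumulative along-route distances ``d_km`` (array)."""
    legs = np.array([
        haversine_km(a[0], a[1], b[0], b[1])
        for a, b in zip(waypoints[:-1], waypoints[1:])
    ])
    cum = np.concatenate([[0.0], np.cumsum(legs)])
    d_km = np.clip(d_km, 0.0, cum[-1])
    lats = np.empty_like(d_km)
    lons = np.empty_like(d_km)
    leg_idx = np.clip(np.searchsorted(cum, d_km, side="right") - 1, 0, len(legs) - 1)
    for i in np.unique(leg_idx):
        mask = leg_idx == i
        frac = (d_km[mask] - cum[i]) / max(legs[i], 1e-12)
        a, b = waypoints[i], waypoints[i + 1]
        la, lo = great_circle_waypoint(a[0], a[1], b[0], b[1], frac)
        lats[mask], lons[mask] = la, lo
    return lats, lons


def _in_range_detections(rng, tag, times, lats, lons, receivers, radius_km, prob):
    rows = []
    r_lat = receivers["lat"].to_numpy()
    r_lon = receivers["lon"].to_numpy()
    r_id = receivers["receiver_id"].to_numpy()
    for j in range(len(receivers)):
        d = haversine_km(lats, lons, r_lat[j], r_lon[j])
        hit = (d <= radius_km) & (rng.random(len(times)) < prob)
        for ts in times[hit]:
            rows.append((tag, ts, r_id[j]))
    return rows


def _beacon_cluster(rng, tag, t0, bi, n_bursts, receivers, lat, lon,
                    radius_km, prob):
    times = np.array([t0 + dt.timedelta(seconds=bi * k) for k in range(n_bursts)])
    lats = np.full(n_bursts, lat)
    lons = np.full(n_bursts, lon)
    return _in_range_detections(rng, tag, times, lats, lons, receivers,
                                radius_km, prob)


def simulate_detections(histories, receivers, config, world=None, rng=None) -> pd.DataFrame:
    """Detection table (tag_id, timestamp, receiver_id), time-sorted."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 47]))
    radius = config.detection_radius_km
    rows = []
    t_min, t_max = None, None
    for h in histories:
        lat0, lon0 = CAPTURE_SITES[h.site]
        phase = float(rng.uniform(0, h.burst_interval))
        # --- stopover beacons (daily, short multi-burst cluster) ---
        last_day = (h.departure_ts.date() if h.departure_ts else h.censor_ts.date())
        day = h.capture_ts.date()
        while day <= last_day:
            t0 = dt.datetime(day.year, day.month, day.day,
                             config.stopover_beacon_hour, 0,
                             tzinfo=dt.timezone.utc) + dt.timedelta(seconds=phase)
            if t0 > h.capture_ts:
                rows += _beacon_cluster(
                    rng, h.tag_id, t0, h.burst_interval,
                    config.stopover_beacon_bursts, receivers, lat0, lon0,
                    radius, config.stopover_detection_prob,
                )
            day += dt.timedelta(days=1)
        # --- flight ---
        if h.departure_ts is not None:
            total_km = route_length_km(h.waypoints)
            duration_s = total_km * 1000.0 / config.airspeed_ms
            step = h.burst_interval * config.burst_stride
            offsets = np.arange(0.0, duration_s + step, step)
            times = np.array([h.departure_ts + dt.timedelta(seconds=float(s))
                              for s in offsets])
            d_km = offsets * config.airspeed_ms / 1000.0
            lats, lons = _route_positions(h.waypoints, d_km)
            if config.wind_drift and world is not None:
                w = world.sample(lat0, lon0, _floor_hour(h.departure_ts))
                lats = lats + w["v10"] * offsets / 111195.0
                lons = lons + w["u10"] * offsets / (111195.0 *
                                                   np.cos(np.radians(lats)))
            rows += _in_range_detections(
                rng, h.tag_id, times, lats, lons, receivers, radius,
                config.detection_prob,
            )
            # --- post-landing dwell beacons ---
            if h.landed:
                end_lat, end_lon = h.waypoints[-1]
                for k in range(1, int(config.landing_dwell_hours) + 1):
                    t0 = h.flight_end_ts + dt.timedelta(hours=k, seconds=phase)
                    rows += _beacon_cluster(
                        rng, h.tag_id, t0, h.burst_interval,
                        config.stopover_beacon_bursts, receivers, end_lat,
                        end_lon, radius, config.stopover_detection_prob,
                    )
        lo = h.capture_ts
        hi = (h.flight_end_ts or h.censor_ts) + dt.timedelta(days=1)
        t_min = lo if t_min is None else min(t_min, lo)
        t_max = hi if t_max is None else max(t_max, hi)

    # --- false positives: Poisson per receiver-hour, real tag ids ---
    if histories and config.false_positive_rate > 0:
        span_h = (t_max - t_min).total_seconds() / 3600.0
        tags = [h.tag_id for h in histories]
        for _, rec in receivers.iterrows():
            n_fp = rng.poisson(config.false_positive_rate * span_h)
            for _ in range(n_fp):
                ts = t_min + dt.timedelta(hours=float(rng.uniform(0, span_h)))
                rows.append((tags[int(rng.integers(0, len(tags)))], ts,
                             rec["receiver_id"]))

    df = pd.DataFrame(rows, columns=COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df = df.sort_values(["timestamp", "tag_id", "receiver_id"],
                        kind="mergesort").reset_index(drop=True)
    return df


def _floor_hour(ts: dt.datetime) -> dt.datetime:
    return ts.replace(minute=0, second=0, microsecond=0)
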