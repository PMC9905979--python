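"""Model input tables: bird-night departure rows and flight covariate rows.

The departure table has one row per bird per night from capture up to and
including the departure night, with weather sampled at the bird's
flight-begin location at that night's sunset hour (rounded to the full
hour) and 24-h changes from the same location.  Flight covariate rows
carry begin- and end-of-flight weather plus the begin-to-end wind changes
for the routing and landing models.
"""

from __future__ import annotations

import datetime as dt
import logging

import pandas as pd

from ..solar import sunset_utc
from .sampling import nearest_rain

log = logging.getLogger(__name__)


def standardize(df: pd.DataFrame, cols):
    """Centre and scale the named columns to one s.d.

    Returns ``(transformed copy, scaling)`` where ``scaling`` maps column
    name to ``(mean, sd)`` so coefficients can be mapped back to natural
    units.  A zero-variance column raises a ``ValueError`` naming it.
    """
    out = df.copy()
    scaling = {}
    for col in cols:
        x = out[col].to_numpy(dtype=float)
        sd = float(x.std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"column {col!r} has zero variance")
        mean = float(x.mean())
        out[col] = (x - mean) / sd
        scaling[col] = (mean, sd)
    return out, scaling


def unstandardize(df: pd.DataFrame, scaling: dict) -> pd.DataFrame:
    """Inverse of :func:`standardize` for the recorded columns."""
    out = df.copy()
    for col, (mean, sd) in scaling.items():
        out[col] = out[col].to_numpy(dtype=float) * sd + mean
    return out


def _night_sunsets(lat, lon, capture_ts: pd.Timestamp, until_ts: pd.Timestamp,
                   max_nights: int = 60):
    """Rounded sunsets for nights 1..N with N the night containing until_ts."""
    sunsets = []
    day = capture_ts.date()
    for n in range(max_nights):
        s = sunset_utc(lat, lon, day + dt.timedelta(days=n))
        sunsets.append(pd.Timestamp(s))
        if s >= until_ts:
            break
    # departure night = last sunset <= departure time; ensure at least one row
    n_dep = sum(1 for s in sunsets if s <= until_ts)
    return sunsets[: max(n_dep, 1)]


def build_departure_table(
    stopovers: pd.DataFrame,
    flights: pd.DataFrame,
    world,
    include_censored: bool = False,
    deployments: pd.DataFrame | None = None,
    censored_nights: int | None = None,
) -> pd.DataFrame:
    """One row per bird-night until (and including) the departure night.

    ``stopovers`` supplies capture times, ``flights`` the first-flight
    begin location and time per bird.  Rows whose rain station is farther
    than the coverage limit are dropped with a logged count.  With
    ``include_censored`` birds without a flight (from ``deployments``)
    contribute event-free rows at their capture location.
    """
    rows = []
    n_missing_rain = 0
    n_dropped_birds = 0
    cap = stopovers.set_index("tag_id")
    for _, fl in flights.sort_values("tag_id").iterrows():
        tag = fl["tag_id"]
        capture_ts = pd.Timestamp(cap.loc[tag, "capture_ts"])
        lat, lon = float(fl["begin_lat"]), float(fl["begin_lon"])
        begin_ts = pd.Timestamp(fl["begin_ts"])
        sunsets = _night_sunsets(lat, lon, capture_ts, begin_ts)
        bird_rows = []
        for n, s in enumerate(sunsets, start=1):
            row = _weather_row(world, lat, lon, s)
            if row is None:
                n_missing_rain += 1
                continue
            row.update({
                "bird": tag,
                "species": fl["species"],
                "year": int(begin_ts.year),
                "doy": int(capture_ts.dayofyear),
                "night": n,
                "sunset": s,
                "event": int(n == len(sunsets)),
            })
            bird_rows.append(row)
        # a bird whose departure-night row lacks coverage is excluded
        # entirely; otherwise it would look censored
        if bird_rows and bird_rows[-1]["event"] == 1:
            rows.extend(bird_rows)
        else:
            n_dropped_birds += 1
    if n_dropped_birds:
        log.warning("excluded %d birds whose departure night lacks rain "
                    "coverage", n_dropped_birds)
    if include_censored:
        if deployments is None:
            raise ValueError("deployments required for censored birds")
        max_night = max((r["night"] for r in rows), default=1)
        n_cens = censored_nights or max_night
        flown = set(flights["tag_id"])
        for _, d in deployments.sort_values("tag_id").iterrows():
            if d["tag_id"] in flown:
                continue
            capture_ts = pd.Timestamp(d["capture_ts"])
            lat, lon = float(d["capture_lat"]), float(d["capture_lon"])
            for n in range(1, n_cens + 1):
                s = pd.Timestamp(sunset_utc(
                    lat, lon, capture_ts.date() + dt.timedelta(days=n - 1)))
                row = _weather_row(world, lat, lon, s)
                if row is None:
                    n_missing_rain += 1
                    continue
                row.update({
                    "bird": d["tag_id"], "species": d["species"],
                    "year": int(capture_ts.year),
                    "doy": int(capture_ts.dayofyear),
                    "night": n, "sunset": s, "event": 0,
                })
                rows.append(row)
    if n_missing_rain:
        log.warning("dropped %d bird-nights without rain coverage", n_missing_rain)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["year_species"] = df["year"].astype(str) + "_" + df["species"]
    return df


def _weather_row(world, lat, lon, when):
    w = world.sample_with_deltas(lat, lon, when)
    rain = nearest_rain(world, lat, lon, when)
    if rain is None:
        return None
    return {
        "u": w["u10"], "v": w["v10"], "temp": w["t2m"], "pressure": w["sp"],
        "cloud": w["tcc"], "rain": rain,
        "du24": w["du24"], "dv24": w["dv24"], "dt24": w["dt24"],
        "dp24": w["dp24"],
    }


def build_flight_covariates(
    flights: pd.DataFrame,
    stopovers: pd.DataFrame,
    world,
) -> pd.DataFrame:
    """Begin/end weather, flight-level wind changes and outcomes per flight.

    The flight-end detection timestamp stands in for the estimated landing
    time.  ``du_flight`` / ``dv_flight`` are end-minus-begin wind changes.
    """
    stop = stopovers.set_index("tag_id")
    rows = []
    for _, fl in flights.sort_values("tag_id").iterrows():
        tag = fl["tag_id"]
        begin_ts = pd.Timestamp(fl["begin_ts"])
        end_ts = pd.Timestamp(fl["end_ts"])
        wb = world.sample_with_deltas(fl["begin_lat"], fl["begin_lon"],
                                      _round_hour(begin_ts))
        we = world.sample_with_deltas(fl["end_lat"], fl["end_lon"],
                                      _round_hour(end_ts))
        rain_end = nearest_rain(world, fl["end_lat"], fl["end_lon"],
                                _round_hour(end_ts))
        rows.append({
            "bird": tag,
            "species": fl["species"],
            "year": int(begin_ts.year),
            "doy_dep": int(begin_ts.dayofyear),
            "doy_end": int(end_ts.dayofyear),
            "u": wb["u10"], "v": wb["v10"], "cloud_begin": wb["tcc"],
            "temp_begin": wb["t2m"], "pressure_begin": wb["sp"],
            "u_end": we["u10"], "v_end": we["v10"], "cloud": we["tcc"],
            "temp_end": we["t2m"], "pressure_end": we["sp"],
            "rain_end": -1 if rain_end is None else rain_end,
            "du_flight": we["u10"] - wb["u10"],
            "dv_flight": we["v10"] - wb["v10"],
            "min_stopover_days": int(stop.loc[tag, "min_stopover_days"]),
            "route": fl["route"],
            "offshore": int(fl["route"] == "offshore"),
            "landed": int(fl["landed"]),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["year_species"] = df["year"].astype(str) + "_" + df["species"]
    return df


def _round_hour(ts: pd.Timestamp) -> pd.Timestamp:
    return (ts + pd.Timedelta(minutes=30)).floor("h")
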