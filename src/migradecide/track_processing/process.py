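"""End-to-end track processing: raw detections to per-bird flight records."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .filtering import filter_false_positives
from .flights import attach_coordinates, segment_flights, select_first_flight, split_trailing_dwell
from .landings import detect_landing
from .routes import classify_route

log = logging.getLogger(__name__)


def process_tracks(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    deployments: pd.DataFrame,
    max_gap_h: float = 7.0,
    min_km: float = 35.0,
    min_receivers: int = 3,
    lat_threshold: float = 54.135,
    lon_threshold: float = 8.08,
    dwell_h: float = 1.0,
    slow_ms: float = 5.0,
    slow_range_km: float = 32.0,
    slow_window_d: float = 3.0,
    filter_kwargs: dict | None = None,
) -> dict:
    """Filter, segment, classify and summarize all tags.

    Returns a dict with ``flights`` (one row per first flight),
    ``landings``, ``stopovers`` (minimum stopover duration per departing
    bird), ``no_flight_tags`` and a ``report`` of record accounting.
    """
    burst_intervals = dict(
        zip(deployments["tag_id"], deployments["burst_interval"])
    )
    filtered, report = filter_false_positives(
        detections, burst_intervals, return_report=True,
        **(filter_kwargs or {}),
    )
    filtered = attach_coordinates(filtered, receivers)
    all_flights = segment_flights(
        filtered, max_gap_h=max_gap_h, min_km=min_km,
        min_receivers=min_receivers,
    )
    first = select_first_flight(all_flights)
    meta = deployments.set_index("tag_id")

    flight_rows, landing_rows, stopover_rows = [], [], []
    for tag, flight in sorted(first.items()):
        flight, post = split_trailing_dwell(flight, dwell_h=dwell_h)
        # post-flight pool: the split-off dwell plus any later detections
        later = filtered.loc[
            (filtered["tag_id"] == tag)
            & (filtered["timestamp"] > flight.end_time)
        ]
        post_pool = pd.concat([post, later]).drop_duplicates()
        route = classify_route(flight, lat_threshold=lat_threshold,
                               lon_threshold=lon_threshold)
        landing = detect_landing(
            flight, post_pool, dwell_h=dwell_h, slow_ms=slow_ms,
            slow_range_km=slow_range_km, window_d=slow_window_d,
        )
        capture_ts = pd.Timestamp(meta.loc[tag, "capture_ts"])
        begin, end = flight.begin, flight.end
        stop_days = int(
            np.floor((flight.begin_time - capture_ts) / pd.Timedelta(days=1))
        )
        flight_rows.append({
            "tag_id": tag,
            "species": meta.loc[tag, "species"],
            "year": flight.begin_time.year,
            "begin_ts": flight.begin_time,
            "begin_lat": begin["lat"],
            "begin_lon": begin["lon"],
            "end_ts": flight.end_time,
            "end_lat": end["lat"],
            "end_lon": end["lon"],
            "distance_km": flight.distance_km,
            "n_receivers": flight.n_receivers,
            "route": route,
            "landed": int(landing is not None),
            "landing_rule": landing.rule if landing else "",
        })
        if landing:
            landing_rows.append({
                "tag_id": tag,
                "rule": landing.rule,
                "receiver_id": landing.receiver_id,
                "timestamp": landing.timestamp,
            })
        stopover_rows.append({
            "tag_id": tag,
            "species": meta.loc[tag, "species"],
            "capture_ts": capture_ts,
            "begin_ts": flight.begin_time,
            "min_stopover_days": max(stop_days, 0),
        })

    no_flight = sorted(set(deployments["tag_id"]) - set(first))
    report.update({
        "n_flights_all": len(all_flights),
        "n_first_flights": len(first),
        "n_no_flight": len(no_flight),
    })
    log.info("track processing report: %s", report)
    return {
        "flights": pd.DataFrame(flight_rows),
        "landings": pd.DataFrame(landing_rows),
        "stopovers": pd.DataFrame(stopover_rows),
        "no_flight_tags": no_flight,
        "report": report,
    }
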