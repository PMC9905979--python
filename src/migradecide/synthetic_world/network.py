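"""Receiver network layout and migration routes.

The geometry mimics a coastal study area on a bight: two capture sites in
the northeast, a chain of coastline receivers running southwest, one
island receiver far offshore, and an island receiver near the far coast
where offshore crossings make landfall.  Offshore routes cut straight
across the bight; onshore routes follow the coastal chain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..geo import haversine_km

CAPTURE_SITES = {
    "north_lagoon": (54.53, 8.88),
    "lake_site": (54.84, 8.78),
}

# (receiver_id, lat, lon, is_coastal, is_helgoland_like)
_CORE_RECEIVERS = [
    ("R_north_lagoon", 54.53, 8.88, False, False),
    ("R_lake_site", 54.84, 8.78, False, False),
    ("C1", 54.45, 8.95, True, False),
    ("C2", 54.25, 8.75, True, False),
    ("C3", 54.00, 8.85, True, False),
    ("C4", 53.85, 8.55, True, False),
    ("C5", 53.75, 8.05, True, False),
    ("C6", 53.60, 7.55, True, False),
    ("C7", 53.55, 7.15, True, False),
    ("HELGO", 54.1833, 7.8833, False, True),
    ("I_WEST", 53.58, 6.92, False, False),
    ("I_MID", 53.65, 7.35, False, False),
]

OFFSHORE_END = (53.55, 6.90)


def build_receivers(config) -> pd.DataFrame:
    """Receiver table: core layout plus random fill-in receivers."""
    rows = list(_CORE_RECEIVERS)
    extra = config.n_receivers - len(rows)
    if extra > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
        lat_min, lat_max, lon_min, lon_max = config.bbox
        for i in range(extra):
            rows.append((
                f"X{i + 1}",
                float(rng.uniform(lat_min, lat_max)),
                float(rng.uniform(lon_min, lon_max)),
                False,
                False,
            ))
    df = pd.DataFrame(
        rows, columns=["receiver_id", "lat", "lon", "is_coastal", "is_helgoland_like"]
    )
    return df


def route_waypoints(site: str, route: str) -> list:
    """Ordered (lat, lon) waypoints for a route from a capture site."""
    start = CAPTURE_SITES[site]
    if route == "offshore":
        return [start, OFFSHORE_END]
    coastal = [(r[1], r[2]) for r in _CORE_RECEIVERS if r[3]]
    return [start] + coastal


def route_length_km(waypoints) -> float:
    legs = [
        haversine_km(a[0], a[1], b[0], b[1])
        for a, b in zip(waypoints[:-1], waypoints[1:])
    ]
    return float(np.sum(legs))
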