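"""Landing detection after a sustained flight.

A landing is assumed when post-flight detections (within a fixed window
after the flight's end) show either (i) dwell — detections at one receiver
spanning more than an hour — or (ii) slow movement — every successive
ground speed below a walking-pace threshold with all detections staying
close to the flight end.  A bird without qualifying post-flight detections
is deemed to have left the study area.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ..geo import ground_speed_ms, haversine_km
from .flights import Flight


@dataclass
class LandingEvent:
    tag_id: str
    rule: str              # "dwell" | "slow-movement"
    receiver_id: str
    timestamp: pd.Timestamp


def detect_landing(
    flight: Flight,
    post_detections: pd.DataFrame,
    dwell_h: float = 1.0,
    slow_ms: float = 5.0,
    slow_range_km: float = 32.0,
    window_d: float = 3.0,
) -> LandingEvent | None:
    """Apply the dwell and slow-movement rules to post-flight detections."""
    end_time = flight.end_time
    post = post_detections
    post = post.loc[
        (post["timestamp"] > end_time)
        & (post["timestamp"] <= end_time + pd.Timedelta(days=window_d))
    ].sort_values(["timestamp", "receiver_id"], kind="mergesort")
    if post.empty:
        return None
    # rule (i): > dwell_h at a single receiver
    for rec, grp in post.groupby("receiver_id", sort=True):
        span = grp["timestamp"].iloc[-1] - grp["timestamp"].iloc[0]
        if span > pd.Timedelta(hours=dwell_h):
            return LandingEvent(
                tag_id=flight.tag_id, rule="dwell", receiver_id=rec,
                timestamp=grp["timestamp"].iloc[0],
            )
    # rule (ii): all slow movements near the flight end
    end = flight.end
    dists = haversine_km(post["lat"].to_numpy(), post["lon"].to_numpy(),
                         end["lat"], end["lon"])
    if (dists < slow_range_km).all() and len(post) >= 2:
        rows = post.to_dict("records")
        speeds_ok = True
        for a, b in zip(rows[:-1], rows[1:]):
            if b["timestamp"] == a["timestamp"]:
                continue
            v = ground_speed_ms(a["lat"], a["lon"], a["timestamp"],
                                b["lat"], b["lon"], b["timestamp"])
            if v >= slow_ms:
                speeds_ok = False
                break
        if speeds_ok:
            first = post.iloc[0]
            return LandingEvent(
                tag_id=flight.tag_id, rule="slow-movement",
                receiver_id=first["receiver_id"], timestamp=first["timestamp"],
            )
    return None
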