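"""Flight segmentation from filtered detections.

A movement chain is a maximal run of consecutive detections of one tag in
which successive detections are separated by less than ``max_gap_h`` hours
(by default the gap rule applies to every adjacent pair; a variant applies
it only between detections at different receivers).  A chain is a flight
iff its cumulative great-circle distance reaches ``min_km`` OR it touches
at least ``min_receivers`` distinct receivers.  Both qualifying quantities
are monotone under chain extension, so maximal chains are exactly the
maximal qualifying sub-chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..geo import haversine_km


@dataclass
class Flight:
    """One continuous movement satisfying the flight rule."""

    tag_id: str
    detections: pd.DataFrame = field(repr=False)
    distance_km: float = 0.0
    n_receivers: int = 0
    is_first_flight: bool = False

    @property
    def begin(self) -> pd.Series:
        return self.detections.iloc[0]

    @property
    def end(self) -> pd.Series:
        return self.detections.iloc[-1]

    @property
    def begin_time(self):
        return self.begin["timestamp"]

    @property
    def end_time(self):
        return self.end["timestamp"]


def attach_coordinates(detections: pd.DataFrame, receivers: pd.DataFrame) -> pd.DataFrame:
    """Join receiver lat/lon (and flags when present) onto detections."""
    cols = ["receiver_id", "lat", "lon"]
    for flag in ("is_coastal", "is_helgoland_like"):
        if flag in receivers.columns:
            cols.append(flag)
    merged = detections.merge(receivers[cols], on="receiver_id", how="left",
                              validate="many_to_one")
    if merged["lat"].isna().any():
        missing = merged.loc[merged["lat"].isna(), "receiver_id"].unique()
        raise ValueError(f"unresolvable receiver ids: {list(missing)[:5]}")
    return merged


def _chain_metrics(chunk: pd.DataFrame):
    lat = chunk["lat"].to_numpy()
    lon = chunk["lon"].to_numpy()
    dist = float(np.sum(haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]))) if len(lat) > 1 else 0.0
    return dist, int(chunk["receiver_id"].nunique())


def segment_flights(
    detections: pd.DataFrame,
    receivers: pd.DataFrame | None = None,
    max_gap_h: float = 7.0,
    min_km: float = 35.0,
    min_receivers: int = 3,
    gap_rule: str = "any",
) -> list:
    """Segment per-tag detections into flights.

    ``gap_rule``: ``"any"`` breaks a chain at every gap >= max_gap_h;
    ``"different_receivers_only"`` breaks only when the two detections are
    at different receivers (same-receiver dwells of any length then stay in
    one chain).
    """
    if gap_rule not in ("any", "different_receivers_only"):
        raise ValueError(f"unknown gap rule {gap_rule!r}")
    if receivers is not None and "lat" not in detections.columns:
        detections = attach_coordinates(detections, receivers)
    flights = []
    max_gap = np.timedelta64(int(max_gap_h * 3600), "s")
    for tag, grp in detections.groupby("tag_id", sort=True):
        grp = grp.sort_values(["timestamp", "receiver_id"], kind="mergesort")
        ts = grp["timestamp"].to_numpy()
        rec = grp["receiver_id"].to_numpy()
        gaps = np.diff(ts)
        breaks = gaps >= max_gap
        if gap_rule == "different_receivers_only":
            breaks &= rec[1:] != rec[:-1]
        bounds = np.concatenate([[0], np.flatnonzero(breaks) + 1, [len(grp)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            chunk = grp.iloc[a:b]
            dist, n_rec = _chain_metrics(chunk)
            if dist >= min_km or n_rec >= min_receivers:
                flights.append(Flight(tag_id=tag, detections=chunk,
                                      distance_km=dist, n_receivers=n_rec))
    return flights


def split_trailing_dwell(flight: Flight, dwell_h: float = 1.0):
    """Separate a stationary tail (dwell at the final receiver) from a flight.

    If the maximal same-receiver suffix of the chain spans more than
    ``dwell_h`` hours, the flight is cut at the first detection of that
    suffix (the arrival) and the remainder is returned as post-flight
    detections.  Returns ``(flight, post_detections)``.
    """
    det = flight.detections
    rec = det["receiver_id"].to_numpy()
    i = len(rec) - 1
    while i > 0 and rec[i - 1] == rec[-1]:
        i -= 1
    suffix = det.iloc[i:]
    span = (suffix["timestamp"].iloc[-1] - suffix["timestamp"].iloc[0])
    if span <= pd.Timedelta(hours=dwell_h) or i == 0:
        return flight, det.iloc[0:0]
    head = det.iloc[: i + 1]
    dist, n_rec = _chain_metrics(head)
    trimmed = Flight(tag_id=flight.tag_id, detections=head, distance_km=dist,
                     n_receivers=n_rec, is_first_flight=flight.is_first_flight)
    return trimmed, det.iloc[i + 1:]


def select_first_flight(flights) -> dict:
    """Earliest flight per tag (ties: earlier end time), marked as first."""
    best = {}
    for fl in flights:
        cur = best.get(fl.tag_id)
        key = (fl.begin_time, fl.end_time)
        if cur is None or key < (cur.begin_time, cur.end_time):
            best[fl.tag_id] = fl
    for fl in best.values():
        fl.is_first_flight = True
    return best
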