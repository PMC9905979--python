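"""Offshore / onshore route classification."""

from __future__ import annotations

from .flights import Flight

OFFSHORE_LAT = 54.135   # flight must begin north of this latitude
OFFSHORE_LON = 8.08     # and end west of this longitude


def classify_route(
    flight: Flight,
    lat_threshold: float = OFFSHORE_LAT,
    lon_threshold: float = OFFSHORE_LON,
) -> str:
    """Classify a flight as ``"offshore"`` or ``"onshore"``.

    Offshore iff the flight begins north of ``lat_threshold`` and ends west
    of ``lon_threshold`` with no coastline-flagged detections strictly
    between the begin and end detections, or iff it includes any detection
    at the far-offshore-island receiver.  Requires ``is_coastal`` and
    ``is_helgoland_like`` flags on the flight's detections.
    """
    det = flight.detections
    for flag in ("is_coastal", "is_helgoland_like"):
        if flag not in det.columns:
            raise ValueError(f"detections lack receiver flag {flag!r}")
    if det["is_helgoland_like"].any():
        return "offshore"
    begin, end = det.iloc[0], det.iloc[-1]
    if begin["lat"] > lat_threshold and end["lon"] < lon_threshold:
        between = det.iloc[1:-1]
        if not between["is_coastal"].any():
            return "offshore"
    return "onshore"
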