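"""Great-circle geometry on the WGS84 mean-radius sphere."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def _validate(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude outside [-180, 180]")


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays; uses the haversine formula on a
    sphere of radius 6371.0088 km.
    """
    _validate(lat1, lon1)
    _validate(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    if np.isscalar(lat1) and np.isscalar(lat2):
        return float(d)
    return d


def ground_speed_ms(lat1, lon1, t1, lat2, lon2, t2) -> float:
    """Implied ground speed (m/s) between two timestamped positions.

    ``t1``/``t2`` are anything convertible to ``numpy.datetime64``; ``t2``
    must be strictly after ``t1``.
    """
    def _to64(t):
        if hasattr(t, "tz_convert") and t.tzinfo is not None:
            t = t.tz_convert("UTC").tz_localize(None)
        elif hasattr(t, "tzinfo") and t.tzinfo is not None:
            import datetime as _dt

            t = t.astimezone(_dt.timezone.utc).replace(tzinfo=None)
        return np.datetime64(t)

    t1 = _to64(t1)
    t2 = _to64(t2)
    dt_s = (t2 - t1) / np.timedelta64(1, "s")
    if dt_s <= 0:
        raise ValueError("elapsed time must be positive for a defined speed")
    return haversine_km(lat1, lon1, lat2, lon2) * 1000.0 / dt_s


def great_circle_waypoint(lat1, lon1, lat2, lon2, frac):
    """Point a fraction ``frac`` of the way along the great circle (degrees).

    ``frac`` may be a scalar or array in [0, 1].
    """
    _validate(lat1, lon1)
    _validate(lat2, lon2)
    frac = np.asarray(frac, dtype=float)
    phi1, lam1 = np.radians(lat1), np.radians(lon1)
    phi2, lam2 = np.radians(lat2), np.radians(lon2)
    d = haversine_km(lat1, lon1, lat2, lon2) / EARTH_RADIUS_KM  # angular dist
    if d < 1e-12:
        lat = np.full_like(frac, lat1, dtype=float)
        lon = np.full_like(frac, lon1, dtype=float)
        return lat, lon
    a = np.sin((1.0 - frac) * d) / np.sin(d)
    b = np.sin(frac * d) / np.sin(d)
    x = a * np.cos(phi1) * np.cos(lam1) + b * np.cos(phi2) * np.cos(lam2)
    y = a * np.cos(phi1) * np.sin(lam1) + b * np.cos(phi2) * np.sin(lam2)
    z = a * np.sin(phi1) + b * np.sin(phi2)
    lat = np.degrees(np.arctan2(z, np.hypot(x, y)))
    lon = np.degrees(np.arctan2(y, x))
    return lat, lon
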