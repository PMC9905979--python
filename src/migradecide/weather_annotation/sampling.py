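"""Point sampling of the gridded weather world and station rain."""

from __future__ import annotations

RAIN_MAX_KM = 20.0


def sample_grid(world, lat: float, lon: float, when) -> dict:
    """Nearest-cell, exact-hour values of all gridded fields (no rain)."""
    return world.sample(lat, lon, when)


def nearest_rain(world, lat: float, lon: float, when, max_km: float = RAIN_MAX_KM):
    """Binary rain at the nearest station, or ``None`` beyond ``max_km``.

    Station ties at identical distance resolve to the lower station_id.
    """
    if len(world.stations) == 0:
        raise ValueError("no precipitation stations available")
    idx, dist = world.nearest_station(lat, lon)
    if dist >= max_km:
        return None
    return world.station_rain(idx, when)
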