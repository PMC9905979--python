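"""Sunset computation from standard solar geometry.

Uses the Julian-century solar-position formulas (geometric mean longitude,
equation of centre, apparent longitude, corrected obliquity) to obtain the
solar declination and equation of time, then the hour-angle sunset
equation at zenith 90.833 deg (refraction plus solar-disc radius), iterated
once so declination is evaluated at the sunset hour.  All output is UTC.
"""

from __future__ import annotations

import datetime as dt
import math

ZENITH_DEG = 90.833
POLAR_LAT_LIMIT = 66.5


def _decl_eqtime(jd: float):
    """Solar declination (rad) and equation of time (min) at Julian day."""
    jc = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = math.radians(m)
    c = (math.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
         + math.sin(2 * mr) * (0.019993 - 0.000101 * jc)
         + math.sin(3 * mr) * 0.000289)
    true_long = l0 + c
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(math.radians(omega))
    eps_r = math.radians(eps)
    decl = math.asin(math.sin(eps_r) * math.sin(math.radians(app_long)))
    y = math.tan(eps_r / 2.0) ** 2
    l0r = math.radians(l0)
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2.0 * ecc * math.sin(mr)
        + 4.0 * ecc * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mr)
    )
    return decl, eqtime


def _julian_day(date: dt.date, utc_minutes: float) -> float:
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    jd0 = math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5
    return jd0 + utc_minutes / 1440.0


def sunset_utc_exact(lat: float, lon: float, date: dt.date) -> dt.datetime:
    """Unrounded UTC sunset for ``date`` at (lat, lon) in decimal degrees.

    Raises ``ValueError`` for |lat| >= 66.5 deg (polar day/night possible)
    or when the sun does not cross the sunset zenith on that date.
    """
    if abs(lat) >= POLAR_LAT_LIMIT:
        raise ValueError("latitude too close to polar circle for sunset logic")
    if abs(lon) > 180.0 or abs(lat) > 90.0:
        raise ValueError("coordinates out of range")
    phi = math.radians(lat)
    utc_minutes = 720.0 - 4.0 * lon  # start at approximate solar noon
    for _ in range(3):
        decl, eqtime = _decl_eqtime(_julian_day(date, utc_minutes))
        cos_ha = (math.cos(math.radians(ZENITH_DEG))
                  / (math.cos(phi) * math.cos(decl))
                  - math.tan(phi) * math.tan(decl))
        if not -1.0 <= cos_ha <= 1.0:
            raise ValueError("no sunset on this date at this latitude")
        ha = math.degrees(math.acos(cos_ha))
        utc_minutes = 720.0 - 4.0 * (lon - ha) - eqtime
    base = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    return base + dt.timedelta(minutes=utc_minutes)


def round_to_hour(t: dt.datetime) -> dt.datetime:
    """Round to the nearest full hour; exactly :30:00 rounds up."""
    t = t.replace(microsecond=0)
    shifted = t + dt.timedelta(minutes=30)
    return shifted.replace(minute=0, second=0)


def sunset_utc(lat: float, lon: float, date: dt.date) -> dt.datetime:
    """UTC sunset rounded to the nearest full hour."""
    return round_to_hour(sunset_utc_exact(lat, lon, date))
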