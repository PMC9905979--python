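"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from first principles (recursions,
brute force, closed forms) and must stay independent of the package code
paths it checks.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np

from migradecide.geo import haversine_km


# ---------------------------------------------------------------------------
# M-spline via the Ramsay recursion
# ---------------------------------------------------------------------------

def mspline_recursion(x: float, knots: np.ndarray, i: int, order: int) -> float:
    """M_{i,order}(x) from the defining recursion on an extended knot vector."""
    if order == 1:
        if knots[i] <= x < knots[i + 1]:
            return 1.0 / (knots[i + 1] - knots[i])
        # closed right end at the last boundary knot
        if x == knots[-1] and knots[i] < knots[i + 1] == knots[-1]:
            return 1.0 / (knots[i + 1] - knots[i])
        return 0.0
    denom = (order - 1) * (knots[i + order] - knots[i])
    if denom == 0:
        return 0.0
    a = (x - knots[i]) * mspline_recursion(x, knots, i, order - 1)
    b = (knots[i + order] - x) * mspline_recursion(x, knots, i + 1, order - 1)
    return order * (a + b) / denom


# ---------------------------------------------------------------------------
# Solar position (Meeus low-accuracy) for the sunset oracle
# ---------------------------------------------------------------------------

def _julian_day(t: dt.datetime) -> float:
    y, m = t.year, t.month
    d = (t.day + t.hour / 24.0 + t.minute / 1440.0 + t.second / 86400.0)
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def solar_altitude_deg(lat: float, lon: float, t: dt.datetime) -> float:
    """Geometric solar altitude via Meeus' low-accuracy solar position."""
    jd = _julian_day(t)
    T = (jd - 2451545.0) / 36525.0
    L0 = (280.46646 + 36000.76983 * T + 0.0003032 * T * T) % 360.0
    M = 357.52911 + 35999.05029 * T - 0.0001537 * T * T
    Mr = math.radians(M)
    C = ((1.914602 - 0.004817 * T - 0.000014 * T * T) * math.sin(Mr)
         + (0.019993 - 0.000101 * T) * math.sin(2 * Mr)
         + 0.000289 * math.sin(3 * Mr))
    true_long = L0 + C
    omega = 125.04 - 1934.136 * T
    lam = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    eps0 = 23.0 + (26.0 + 21.448 / 60.0) / 60.0 - (46.8150 * T) / 3600.0
    eps = eps0 + 0.00256 * math.cos(math.radians(omega))
    lam_r, eps_r = math.radians(lam), math.radians(eps)
    decl = math.asin(math.sin(eps_r) * math.sin(lam_r))
    ra = math.degrees(math.atan2(math.cos(eps_r) * math.sin(lam_r),
                                 math.cos(lam_r))) % 360.0
    # Greenwich mean sidereal time in degrees
    gmst = (280.46061837 + 360.98564736629 * (jd - 2451545.0)
            + 0.000387933 * T * T) % 360.0
    ha = math.radians((gmst + lon - ra) % 360.0)
    phi = math.radians(lat)
    alt = math.asin(math.sin(phi) * math.sin(decl)
                    + math.cos(phi) * math.cos(decl) * math.cos(ha))
    return math.degrees(alt)


def sunset_bisection(lat: float, lon: float, date: dt.date) -> dt.datetime:
    """Evening crossing of -0.833 deg altitude found by bisection (UTC)."""
    base = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    solar_noon_utc = 12.0 - lon / 15.0

    def alt(hours):
        return solar_altitude_deg(lat, lon, base + dt.timedelta(hours=hours)) + 0.833

    lo, hi = solar_noon_utc, solar_noon_utc + 11.0
    if not (alt(lo) > 0 > alt(hi)):
        raise ValueError("no evening crossing bracketed")
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if alt(mid) > 0:
            lo = mid
        else:
            hi = mid
    return base + dt.timedelta(hours=0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# Exhaustive flight segmentation on toy inputs
# ---------------------------------------------------------------------------

def exhaustive_flights(df, max_gap_h=7.0, min_km=35.0, min_receivers=3):
    """All maximal qualifying contiguous sub-chains, by brute force.

    ``df`` must already be sorted by (timestamp, receiver_id) for one tag.
    Returns a set of (start, end) positional index pairs.
    """
    ts = df["timestamp"].to_numpy()
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    rec = df["receiver_id"].to_numpy()
    n = len(df)
    max_gap = np.timedelta64(int(max_gap_h * 3600), "s")

    def valid(i, j):
        return all(ts[k + 1] - ts[k] < max_gap for k in range(i, j))

    def qualifies(i, j):
        dist = sum(
            haversine_km(lat[k], lon[k], lat[k + 1], lon[k + 1])
            for k in range(i, j)
        )
        return dist >= min_km or len(set(rec[i: j + 1])) >= min_receivers

    good = {
        (i, j)
        for i in range(n)
        for j in range(i, n)
        if valid(i, j) and qualifies(i, j)
    }
    maximal = {
        (i, j)
        for (i, j) in good
        if not any(
            (a <= i and j <= b and (a, b) != (i, j) and valid(a, b))
            for (a, b) in good
        )
    }
    return maximal


# ---------------------------------------------------------------------------
# Misc closed forms
# ---------------------------------------------------------------------------

def binomial_ci_halfwidth(p: float, n: int, z: float = 3.0) -> float:
    return z * math.sqrt(p * (1 - p) / n)
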