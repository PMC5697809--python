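"""Independent solar-position oracle (NOAA spreadsheet algorithm).

Julian-century polynomial formulation of the sun's position (geometric
mean longitude / anomaly, equation of center, apparent longitude,
obliquity with nutation correction), as published in the NOAA solar
calculator.  Deliberately a different algorithm from the package's
Spencer Fourier series, so the two can cross-check each other to within
a couple of minutes.  Test-only code.
"""

from __future__ import annotations

import math
from datetime import date, timedelta


def _julian_day(y: int, m: int, d: float) -> float:
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def solar_position(year: int, month: int, day: int, lat_deg: float, lon_deg: float):
    """NOAA solar quantities for local noon of a calendar date.

    Returns a dict with declination (deg), equation of time (min), and
    transit / sunrise / sunset as fractional hours UTC.  ``lon_deg`` is
    positive east.
    """
    jd = _julian_day(year, month, day + 0.5)  # 12:00 UT
    t = (jd - 2451545.0) / 36525.0

    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mr = math.radians(m)
    c = (
        math.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mr) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))

    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(math.radians(omega))

    decl = math.degrees(
        math.asin(math.sin(math.radians(eps)) * math.sin(math.radians(app_long)))
    )

    y = math.tan(math.radians(eps / 2.0)) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2 * e * math.sin(mr)
        + 4 * e * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * mr)
    )

    phi = math.radians(lat_deg)
    dr = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(90.833)) / (math.cos(phi) * math.cos(dr))
        - math.tan(phi) * math.tan(dr)
    )
    cos_ha = min(1.0, max(-1.0, cos_ha))
    ha = math.degrees(math.acos(cos_ha))

    noon_utc_min = 720.0 - 4.0 * lon_deg - eot
    return {
        "declination_deg": decl,
        "eot_min": eot,
        "transit_utc_h": noon_utc_min / 60.0,
        "sunrise_utc_h": (noon_utc_min - 4.0 * ha) / 60.0,
        "sunset_utc_h": (noon_utc_min + 4.0 * ha) / 60.0,
    }


def day_of_year_to_date(year: int, doy: int) -> date:
    return date(year, 1, 1) + timedelta(days=doy - 1)
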