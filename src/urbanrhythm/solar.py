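"""Solar ephemeris in zone clock time: the cues calling activity entrains to.

Declination and the equation of time come from Spencer's low-precision
Fourier series (accurate to a fraction of a minute, which is all a
minutes-scale behavioural analysis needs).  From those follow local sun
transit (solar noon), sunrise and sunset at the civil zenith 90.833 deg
(refraction + solar radius), and solar midnight — the midpoint between
sunset and the next sunrise, numerically indistinguishable (<1 min) from
transit + 12 h.

Because study-city longitudes are masked as offsets from a band reference
point, every function takes longitude relative to a configurable reference
meridian; clock conversion (UTC offset, daylight saving) is carried by
:class:`ClockRules`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Zenith angle for sunrise/sunset (civil standard: refraction + radius).
SUNSET_ZENITH_DEG = 90.833

#: Minutes of clock time per degree of longitude (24 h * 60 / 360 deg).
MINUTES_PER_DEGREE = 4.0

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class ClockRules:
    """Zone clock conventions: base UTC offset and a DST window.

    Defaults model a European UTC+1 zone in 2007: DST (+1 h) in force from
    day 84 (Mar 25) through day 301 (Oct 28), switching at the day
    boundary.  The study country's zone is masked, so everything is
    configurable.
    """

    base_utc_offset_h: float = 1.0
    dst_start_day: int = 84
    dst_end_day: int = 301
    dst_offset_h: float = 1.0
    reference_meridian_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.dst_start_day >= self.dst_end_day:
            raise ValueError("dst_start_day must precede dst_end_day")

    def dst_active(self, day: int) -> bool:
        return self.dst_start_day <= day <= self.dst_end_day

    def utc_offset_h(self, day: int) -> float:
        return self.base_utc_offset_h + (self.dst_offset_h if self.dst_active(day) else 0.0)

    def absolute_longitude(self, rel_longitude_deg: float) -> float:
        return self.reference_meridian_deg + rel_longitude_deg


#: DST-free rules (handy for purely astronomical comparisons).
NO_DST = ClockRules(base_utc_offset_h=1.0, dst_start_day=1, dst_end_day=2, dst_offset_h=0.0)


def _fractional_year(day: int | np.ndarray) -> np.ndarray:
    # gamma at local noon of day d; a constant intra-day offset is
    # irrelevant at minute precision
    return 2.0 * np.pi * (np.asarray(day, dtype=float) - 1.0 + 0.5) / DAYS_PER_YEAR


def solar_declination(day: int | np.ndarray) -> float | np.ndarray:
    """Solar declination in degrees for an ordinal day (1..365).

    Spencer series; smooth annual curve peaking near +/-23.44 deg at the
    solstices.
    """
    g = _fractional_year(day)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    out = np.degrees(decl)
    return float(out) if np.isscalar(day) else out


def equation_of_time(day: int | np.ndarray) -> float | np.ndarray:
    """Equation of time in minutes (apparent minus mean solar time)."""
    g = _fractional_year(day)
    eot = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    return float(eot) if np.isscalar(day) else eot


def sun_transit(
    rel_longitude_deg: float, day: int, rules: ClockRules = ClockRules()
) -> float:
    """Clock hour of local solar noon (sun crossing the city's meridian)."""
    lon = rules.absolute_longitude(rel_longitude_deg)
    return (
        12.0
        - equation_of_time(day) / 60.0
        - lon / 15.0
        + rules.utc_offset_h(day)
    )


def sunrise_sunset(
    latitude_deg: float,
    rel_longitude_deg: float,
    day: int,
    rules: ClockRules = ClockRules(),
) -> tuple[float, float]:
    """Sunrise and sunset clock hours at the civil zenith.

    Hour angle from cos H = (cos z - sin phi sin delta)/(cos phi cos delta);
    polar day/night (|cos H| > 1) raises, but cannot occur at the 37-43 N
    study latitudes.
    """
    phi = np.radians(latitude_deg)
    delta = np.radians(solar_declination(day))
    z = np.radians(SUNSET_ZENITH_DEG)
    cos_h = (np.cos(z) - np.sin(phi) * np.sin(delta)) / (np.cos(phi) * np.cos(delta))
    if abs(cos_h) > 1.0:
        raise ValueError(
            f"no sunrise/sunset at latitude {latitude_deg} on day {day}"
        )
    half_day_h = np.degrees(np.arccos(cos_h)) / 15.0
    transit = sun_transit(rel_longitude_deg, day, rules)
    return transit - half_day_h, transit + half_day_h


def day_length_h(
    latitude_deg: float, day: int, rules: ClockRules = ClockRules()
) -> float:
    rise, set_ = sunrise_sunset(latitude_deg, 0.0, day, rules)
    return set_ - rise


def solar_midnight(
    latitude_deg: float,
    rel_longitude_deg: float,
    day: int,
    rules: ClockRules = ClockRules(),
) -> float:
    """Clock hour of solar midnight: midpoint of sunset(d) and sunrise(d+1).

    Values past civil midnight exceed 24.  Day 365 wraps to day 1 for the
    next sunrise (sub-minute effect).  Agrees with transit + 12 h to
    within a minute on all study days.
    """
    _, sunset = sunrise_sunset(latitude_deg, rel_longitude_deg, day, rules)
    next_day = day + 1 if day < DAYS_PER_YEAR else 1
    next_rise, _ = sunrise_sunset(latitude_deg, rel_longitude_deg, next_day, rules)
    # the whole night is expressed on day-d's clock: if the DST state
    # changes on the next day, keep this day's UTC offset for the sunrise
    next_rise += rules.utc_offset_h(day) - rules.utc_offset_h(next_day)
    return 0.5 * (sunset + (next_rise + 24.0))


def transit_delay(rel_lon_a_deg: float, rel_lon_b_deg: float) -> float:
    """Sun-transit delay of meridian a after meridian b, in minutes.

    Earth turns 1 degree every 4 minutes, so a city 1 degree west of
    another sees solar events 4 minutes later: delay = -4 (lon_a - lon_b),
    positive when a lies west of b.  Antisymmetric.
    """
    return -MINUTES_PER_DEGREE * (rel_lon_a_deg - rel_lon_b_deg)


def ephemeris_table(
    latitude_deg: float,
    rel_longitude_deg: float,
    days=range(1, DAYS_PER_YEAR + 1),
    rules: ClockRules = ClockRules(),
) -> pd.DataFrame:
    """Daily ephemeris for one location across the year."""
    rows = []
    for d in days:
        rise, set_ = sunrise_sunset(latitude_deg, rel_longitude_deg, d, rules)
        rows.append(
            {
                "lat": latitude_deg,
                "lon": rel_longitude_deg,
                "day": d,
                "declination_deg": solar_declination(d),
                "eot_min": equation_of_time(d),
                "sunrise_h": rise,
                "transit_h": sun_transit(rel_longitude_deg, d, rules),
                "sunset_h": set_,
                "solar_midnight_h": solar_midnight(
                    latitude_deg, rel_longitude_deg, d, rules
                ),
            }
        )
    return pd.DataFrame(rows)


def interior_extrema(
    values: np.ndarray,
    jump_threshold: float = 0.4,
    window: int = 5,
) -> tuple[list[int], list[int]]:
    """Locate interior local minima and maxima of a daily annual curve.

    DST introduces step discontinuities; day-to-day differences larger
    than ``jump_threshold`` (hours) split the curve into continuous
    segments, and extrema are sought only strictly inside a segment, as
    points minimal/maximal over +/-``window`` neighbouring days of that
    segment.  Returns (minima_days, maxima_days) as 1-based day indices.
    """
    v = np.asarray(values, dtype=float)
    breaks = np.where(np.abs(np.diff(v)) > jump_threshold)[0] + 1
    segments = np.split(np.arange(v.size), breaks)
    minima: list[int] = []
    maxima: list[int] = []
    for seg in segments:
        if seg.size < 3:
            continue
        for pos in range(1, seg.size - 1):
            idx = seg[pos]
            neigh = v[seg[max(0, pos - window) : pos + window + 1]]
            here, left, right = v[idx], v[seg[pos - 1]], v[seg[pos + 1]]
            if here <= left and here <= right and here == neigh.min() and here < neigh.max():
                if not minima or idx + 1 - minima[-1] > window:
                    minima.append(idx + 1)
            elif here >= left and here >= right and here == neigh.max() and here > neigh.min():
                if not maxima or idx + 1 - maxima[-1] > window:
                    maxima.append(idx + 1)
    return minima, maxima
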