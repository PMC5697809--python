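"""Band-level timing averages, low-activity periods, and mid-sleep times.

Within a latitudinal band, per-city daily timing series are first
*collapsed*: each city's mean first/last-call times are advanced by its
sun-transit delay relative to the band reference, so that solar-entrained
cities coincide, then averaged (unweighted) across cities per day.  The
band curves are compared against the annual solar-midnight curve of the
reference location.

Per cohort (age bin x gender x weekday), the period of low calling
activity T_LCA is the elapsed time from the mean last-call time t_L of one
activity day to the mean first-call time t_F of the next, and the
mid-sleep proxy is t_mid = (t_L + t_F - 24)/2, with t_L kept on the 0-24+
clock of its day (values past civil midnight exceed 24) so the formula
applies verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from urbanrhythm import activity, solar
from urbanrhythm.cdr_io import City

logger = logging.getLogger(__name__)

DEFAULT_MIN_COHORT_USERS = 50

#: Default cohort age bins: 2-year bins spanning ages 18-80.
DEFAULT_AGE_BINS: list[tuple[int, int]] = [(lo, lo + 2) for lo in range(18, 80, 2)]


def collapse_band(
    timing: pd.DataFrame,
    cities: Sequence[City],
    reference_city: str,
) -> pd.DataFrame:
    """Advance each city's timing series by its transit delay to the reference.

    ``timing`` has columns ``city, day, t_F, t_L`` (extended hours).  A
    city delayed by its longitude (transit_delay > 0, i.e. west of the
    reference) has its times moved *earlier* by that amount, so that after
    the shift purely solar-entrained cities coincide.  Cities absent from
    ``cities`` (no longitude) are dropped with a log message.
    """
    lons = {c.id: c.rel_longitude for c in cities}
    if reference_city not in lons:
        raise ValueError(f"reference city {reference_city!r} has no longitude")
    known = timing["city"].isin(lons)
    if (~known).any():
        logger.warning(
            "dropping %d rows for cities without longitude", int((~known).sum())
        )
    out = timing[known].copy()
    delay_h = out["city"].map(
        {c: solar.transit_delay(lon, lons[reference_city]) / 60.0
         for c, lon in lons.items()}
    )
    out["t_F"] = out["t_F"] - delay_h
    out["t_L"] = out["t_L"] - delay_h
    return out


def band_average(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-day mean of collapsed city series.

    Returns columns ``day, tF_bar, tL_bar, n_cities``.  Cities are not
    population-weighted; the band average is a plain mean.
    """
    grouped = collapsed.groupby("day").agg(
        tF_bar=("t_F", "mean"),
        tL_bar=("t_L", "mean"),
        n_cities=("city", "nunique"),
    )
    return grouped.reset_index()


def filter_holidays(series: pd.DataFrame, holiday_days: set[int]) -> pd.DataFrame:
    """Drop rows whose activity day is a holiday; logs how many."""
    keep = ~series["day"].isin(holiday_days)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filtered %d holiday rows", n_dropped)
    return series[keep].reset_index(drop=True)


def low_activity_period(t_l: float, t_f_next: float) -> float:
    """Elapsed hours from last call (day d) to first call (day d+1).

    ``t_l`` is on day-d's 0-24+ clock (17 <= t_l < 28, past-midnight
    values above 24); ``t_f_next`` is a morning hour of the next day.
    """
    t_lca = (t_f_next + 24.0) - t_l
    if t_lca <= 0:
        raise ValueError(
            f"non-positive low-activity period from t_L={t_l}, t_F={t_f_next}"
        )
    return t_lca


def mid_sleep(t_l: float, t_f_next: float) -> float:
    """Population mid-sleep proxy t_mid = (t_L + t_F - 24)/2, clock hours.

    With t_L on the 0-24+ clock the formula needs no case-splitting and
    equals the midpoint of the [t_L, t_F + 24] interval mapped back to a
    0-24 clock.
    """
    return ((t_l + t_f_next - 24.0) / 2.0) % 24.0


@dataclass(frozen=True)
class CohortKey:
    age_lo: int
    age_hi: int
    gender: str
    weekday: int


def cohort_metrics(
    calls: pd.DataFrame,
    subscribers: pd.DataFrame,
    age_bins: Sequence[tuple[int, int]] = tuple(DEFAULT_AGE_BINS),
    weekdays: Sequence[int] = tuple(range(7)),
    min_users: int = DEFAULT_MIN_COHORT_USERS,
    pool_mon_thu: bool = False,
    city: str | None = None,
    bin_width_min: float = activity.DEFAULT_BIN_WIDTH_MIN,
) -> pd.DataFrame:
    """Cohort-resolved t_F, t_L, T_LCA and t_mid.

    ``calls`` must carry ``caller_id, day, weekday, extended_hour``; the
    subscriber table supplies age and gender.  For a weekday-w row, last
    calls are pooled over activity days with weekday w and first calls
    over days with weekday w+1 — the morning that ends that night's
    low-activity period.  Means are taken over pooled binned
    distributions.  Cohorts whose smaller window has fewer than
    ``min_users`` events are suppressed (logged).  With ``pool_mon_thu``
    the Monday-Thursday nights collapse into one row (weekday coded 0).
    """
    demo = subscribers.set_index("id")[["age", "gender"]]
    merged = calls.join(demo, on="caller_id")
    merged = merged[merged["age"].notna() & merged["gender"].isin(["female", "male"])]

    first = activity.extract_first_calls(merged)
    last = activity.extract_last_calls(merged)
    day_weekday = dict(zip(calls["day"], calls["weekday"]))
    for df in (first, last):
        df["weekday"] = df["day"].map(day_weekday)
        df["age"] = df["caller_id"].map(demo["age"])
        df["gender"] = df["caller_id"].map(demo["gender"])

    def night_key(wd: pd.Series) -> pd.Series:
        return wd.where(~(pool_mon_thu & wd.isin([0, 1, 2, 3])), 0)

    # the morning ending a weekday-w night has weekday w+1
    first = first.copy()
    first["night_weekday"] = (first["weekday"] - 1) % 7
    first["night_weekday"] = night_key(first["night_weekday"])
    last = last.copy()
    last["night_weekday"] = night_key(last["weekday"])

    rows = []
    requested = sorted({0 if (pool_mon_thu and w <= 3) else w for w in weekdays})
    for age_lo, age_hi in age_bins:
        for gender in ("female", "male"):
            f_cohort = first[
                (first["age"] >= age_lo) & (first["age"] < age_hi)
                & (first["gender"] == gender)
            ]
            l_cohort = last[
                (last["age"] >= age_lo) & (last["age"] < age_hi)
                & (last["gender"] == gender)
            ]
            for wd in requested:
                f_times = f_cohort.loc[f_cohort["night_weekday"] == wd, "t"]
                l_times = l_cohort.loc[l_cohort["night_weekday"] == wd, "t"]
                n_users = int(min(f_times.size, l_times.size))
                if n_users < min_users:
                    logger.info(
                        "cohort [%d,%d) %s weekday %d suppressed (%d users)",
                        age_lo, age_hi, gender, wd, n_users,
                    )
                    continue
                p_f = activity.build_distribution(
                    f_times.to_numpy(), activity.MORNING_WINDOW, bin_width_min
                )
                p_l = activity.build_distribution(
                    l_times.to_numpy(), activity.NIGHT_WINDOW, bin_width_min
                )
                t_f = activity.mean_time(p_f)
                t_l = activity.mean_time(p_l)
                rows.append(
                    {
                        "city": city,
                        "age_lo": age_lo,
                        "age_hi": age_hi,
                        "gender": gender,
                        "weekday": wd,
                        "t_F": t_f,
                        "t_L": t_l,
                        "T_LCA": low_activity_period(t_l, t_f),
                        "t_mid": mid_sleep(t_l, t_f),
                        "n_users": n_users,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "city", "age_lo", "age_hi", "gender", "weekday",
            "t_F", "t_L", "T_LCA", "t_mid", "n_users",
        ],
    )


def solar_comparison_report(
    band_series: pd.DataFrame,
    latitude_deg: float,
    rel_longitude_deg: float,
    rules: solar.ClockRules = solar.ClockRules(),
) -> pd.DataFrame:
    """Align band timing curves with the reference location's solar curves.

    One row per day with ``tF_bar``, ``tL_bar``, solar midnight and
    sunrise in zone clock time, plus boolean columns marking interior
    extrema of each curve (DST steps are not counted as extrema).
    """
    days = band_series["day"].to_numpy()
    rises, midnights = [], []
    for d in days:
        rise, _ = solar.sunrise_sunset(latitude_deg, rel_longitude_deg, int(d), rules)
        rises.append(rise)
        midnights.append(
            solar.solar_midnight(latitude_deg, rel_longitude_deg, int(d), rules)
        )
    out = band_series[["day", "tF_bar", "tL_bar"]].copy()
    out["solar_midnight"] = midnights
    out["sunrise"] = rises
    for col in ("tF_bar", "tL_bar", "solar_midnight", "sunrise"):
        minima, maxima = solar.interior_extrema(out[col].to_numpy())
        day_list = out["day"].tolist()
        min_days = {day_list[i - 1] for i in minima}
        max_days = {day_list[i - 1] for i in maxima}
        out[f"{col}_is_min"] = out["day"].isin(min_days)
        out[f"{col}_is_max"] = out["day"].isin(max_days)
    return out
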