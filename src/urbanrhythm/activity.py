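"""Activity days, first/last-call windows, and binned call-time distributions.

Night-time calling activity is nearly null around 04:00, so an analysis
"day" runs from 04:00 of a calendar day to 03:59 of the next.  Times are
expressed in *extended hours*: hours since midnight of the day's opening
calendar date, in [4, 28), where 24-28 encodes 00:00-03:59 of the next
calendar day.

Three distributions are built per city and day: P_all over every outgoing
call in the day, P_F over each user's *first* call in the morning window
[5, 16), and P_L over each user's *last* call in the night window [17, 28).
Both windows are 11 h long and cannot share a call.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

#: Half-open first-call ("morning") window, extended hours.
MORNING_WINDOW = (5.0, 16.0)
#: Half-open last-call ("night") window, extended hours.
NIGHT_WINDOW = (17.0, 28.0)
#: Full activity-day window.
DAY_WINDOW = (4.0, 28.0)

DEFAULT_BIN_WIDTH_MIN = 5.0

DAY_START_HOUR = 4


class OutOfStudyError(ValueError):
    """Timestamp falls before the first activity day of the study year."""


@dataclass(frozen=True)
class ActivityDay:
    """Placement of a timestamp inside the 04:00-anchored analysis day."""

    day: int  # ordinal day of year (1..365) whose 04:00 opens the day
    extended_hour: float  # in [4, 28)

    def __post_init__(self) -> None:
        if not (4.0 <= self.extended_hour < 28.0):
            raise ValueError(f"extended hour {self.extended_hour} outside [4, 28)")


def assign_activity_day(ts: datetime | pd.Timestamp) -> ActivityDay:
    """Map a zone-local timestamp to its activity day and extended hour."""
    ts = pd.Timestamp(ts)
    hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0 + ts.microsecond / 3.6e9
    if hour >= DAY_START_HOUR:
        return ActivityDay(day=int(ts.dayofyear), extended_hour=hour)
    prev = ts.normalize() - pd.Timedelta(days=1)
    if prev.year != ts.year:
        raise OutOfStudyError(
            f"{ts} precedes the first activity day of year {ts.year}"
        )
    return ActivityDay(day=int(prev.dayofyear), extended_hour=hour + 24.0)


def assign_activity_days(starts: pd.Series) -> pd.DataFrame:
    """Vectorized :func:`assign_activity_day` over a timestamp Series.

    Returns columns ``day``, ``extended_hour`` and ``weekday`` (Monday=0,
    weekday of the calendar date that opens the activity day).  Timestamps
    in [00:00, 04:00) of Jan 1 raise :class:`OutOfStudyError`.
    """
    starts = pd.to_datetime(starts)
    hour = (
        starts.dt.hour
        + starts.dt.minute / 60.0
        + starts.dt.second / 3600.0
        + starts.dt.microsecond / 3.6e9
    )
    early = hour < DAY_START_HOUR
    anchor = starts.dt.normalize().where(~early, starts.dt.normalize() - pd.Timedelta(days=1))
    if (anchor.dt.year != starts.dt.year).any():
        raise OutOfStudyError("timestamps before Jan 1 04:00 are outside the study year")
    return pd.DataFrame(
        {
            "day": anchor.dt.dayofyear.astype(int),
            "extended_hour": hour + early.astype(float) * 24.0,
            "weekday": anchor.dt.weekday.astype(int),
        },
        index=starts.index,
    )


@dataclass
class BinnedDistribution:
    """A normalized histogram of call times over a time-of-day window.

    ``probs`` sums to 1 when ``n_events > 0``; an empty distribution keeps
    all-zero probabilities and is flagged by ``n_events == 0``.
    """

    window: tuple[float, float]
    bin_width_min: float
    probs: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        n_bins = _n_bins(self.window, self.bin_width_min)
        if self.probs.shape != (n_bins,):
            raise ValueError(
                f"expected {n_bins} bins for window {self.window} at "
                f"{self.bin_width_min} min, got {self.probs.shape}"
            )
        if (self.probs < 0).any():
            raise ValueError("negative probability mass")
        if self.n_events > 0 and abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {self.probs.sum()}, not 1")

    @property
    def n_bins(self) -> int:
        return self.probs.size

    @property
    def is_empty(self) -> bool:
        return self.n_events == 0

    def bin_edges(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_bins + 1) * self.bin_width_min / 60.0

    def bin_centers(self) -> np.ndarray:
        edges = self.bin_edges()
        return 0.5 * (edges[:-1] + edges[1:])

    def same_binning(self, other: "BinnedDistribution") -> bool:
        return (
            self.window == other.window
            and self.bin_width_min == other.bin_width_min
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_start_hour": self.bin_edges()[:-1], "prob": self.probs}
        )


def _n_bins(window: tuple[float, float], bin_width_min: float) -> int:
    span_min = (window[1] - window[0]) * 60.0
    n = span_min / bin_width_min
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"window span {span_min} min not divisible by bin width {bin_width_min}"
        )
    return int(round(n))


def build_distribution(
    times,
    window: tuple[float, float],
    bin_width_min: float = DEFAULT_BIN_WIDTH_MIN,
) -> BinnedDistribution:
    """Histogram extended-hour times over ``window`` and normalize.

    All times must lie in the half-open window; empty input yields an
    all-zero distribution with ``n_events = 0``.
    """
    times = np.asarray(times, dtype=float)
    n_bins = _n_bins(window, bin_width_min)
    if times.size == 0:
        return BinnedDistribution(window, bin_width_min, np.zeros(n_bins), 0)
    if (times < window[0]).any() or (times >= window[1]).any():
        bad = times[(times < window[0]) | (times >= window[1])]
        raise ValueError(f"times outside window {window}: {bad[:5]}")
    idx = np.floor((times - window[0]) * 60.0 / bin_width_min).astype(int)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return BinnedDistribution(window, bin_width_min, counts / counts.sum(), times.size)


def mean_time(dist: BinnedDistribution) -> float:
    """Probability-weighted mean of bin centers, in extended hours."""
    if dist.is_empty:
        raise ValueError("mean time of an empty distribution is undefined")
    return float(np.dot(dist.probs, dist.bin_centers()))


# ---------------------------------------------------------------------------
# Per-user window extraction and daily timing series
# ---------------------------------------------------------------------------

def _window_calls(calls: pd.DataFrame, window: tuple[float, float]) -> pd.DataFrame:
    t = calls["extended_hour"]
    return calls[(t >= window[0]) & (t < window[1])]


def extract_first_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-user earliest call in the morning window, per activity day.

    ``calls`` must carry ``caller_id``, ``day`` and ``extended_hour``
    columns (see :func:`assign_activity_days`).  Users without a morning
    call on a given day are simply absent.
    """
    morning = _window_calls(calls, MORNING_WINDOW)
    grouped = morning.groupby(["caller_id", "day"], sort=False)["extended_hour"].min()
    return grouped.reset_index().rename(columns={"extended_hour": "t"})


def extract_last_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-user latest call in the night window, per activity day."""
    night = _window_calls(calls, NIGHT_WINDOW)
    grouped = night.groupby(["caller_id", "day"], sort=False)["extended_hour"].max()
    return grouped.reset_index().rename(columns={"extended_hour": "t"})


def daily_timing_series(
    calls: pd.DataFrame,
    year: int,
    city: str | None = None,
) -> pd.DataFrame:
    """Mean first- and last-call times per activity day.

    Means are taken over raw per-user times (one first and one last call
    per user per day).  Returns one row per day present in either window:
    ``city, day, weekday, t_F, t_L, n_users_F, n_users_L``; a day with no
    events in one of the windows carries NaN there.
    """
    first = extract_first_calls(calls).groupby("day")["t"].agg(["mean", "size"])
    last = extract_last_calls(calls).groupby("day")["t"].agg(["mean", "size"])
    out = first.rename(columns={"mean": "t_F", "size": "n_users_F"}).join(
        last.rename(columns={"mean": "t_L", "size": "n_users_L"}), how="outer"
    )
    out = out.reset_index()
    jan1 = pd.Timestamp(year, 1, 1)
    out["weekday"] = [(jan1 + pd.Timedelta(days=int(d) - 1)).weekday() for d in out["day"]]
    out["city"] = city
    out["n_users_F"] = out["n_users_F"].fillna(0).astype(int)
    out["n_users_L"] = out["n_users_L"].fillna(0).astype(int)
    return out[["city", "day", "weekday", "t_F", "t_L", "n_users_F", "n_users_L"]]


def daily_distributions(
    calls: pd.DataFrame,
    which: str,
    bin_width_min: float = DEFAULT_BIN_WIDTH_MIN,
) -> dict[int, BinnedDistribution]:
    """Per-day first-call (P_F) or last-call (P_L) distributions.

    ``which`` is ``"first"`` or ``"last"``; keys are activity-day indices.
    """
    if which == "first":
        per_user, window = extract_first_calls(calls), MORNING_WINDOW
    elif which == "last":
        per_user, window = extract_last_calls(calls), NIGHT_WINDOW
    else:
        raise ValueError(f"which must be 'first' or 'last', got {which!r}")
    return {
        int(day): build_distribution(group["t"].to_numpy(), window, bin_width_min)
        for day, group in per_user.groupby("day", sort=True)
    }


def weekday_pooled_distributions(
    calls: pd.DataFrame,
    which: str,
    bin_width_min: float = DEFAULT_BIN_WIDTH_MIN,
) -> dict[int, BinnedDistribution]:
    """Per-weekday first/last-call distributions pooled across weeks.

    Calling timings differ systematically by day of the week, so pooling
    is done separately per weekday; ``calls`` must carry a ``weekday``
    column.  Keys are weekday indices (Monday=0).  Pooling trades daily
    resolution for much larger per-distribution samples.
    """
    if which == "first":
        per_user, window = extract_first_calls(calls), MORNING_WINDOW
    elif which == "last":
        per_user, window = extract_last_calls(calls), NIGHT_WINDOW
    else:
        raise ValueError(f"which must be 'first' or 'last', got {which!r}")
    day_weekday = dict(zip(calls["day"], calls["weekday"]))
    per_user = per_user.assign(weekday=per_user["day"].map(day_weekday))
    return {
        int(wd): build_distribution(group["t"].to_numpy(), window, bin_width_min)
        for wd, group in per_user.groupby("weekday", sort=True)
    }


def all_calls_distribution(
    calls: pd.DataFrame,
    bin_width_min: float = DEFAULT_BIN_WIDTH_MIN,
) -> BinnedDistribution:
    """P_all pooled over every call in ``calls``, on the full-day window."""
    return build_distribution(
        calls["extended_hour"].to_numpy(), DAY_WINDOW, bin_width_min
    )
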