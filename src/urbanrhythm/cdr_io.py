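"""Call-detail-record data model, CSV I/O, and residence filtering.

A CDR row is one outgoing call: caller, callee, zone-local start timestamp,
and duration in seconds.  Subscribers carry demographics (age, gender) and
two residence proxies — the postal-code centroid and the most-accessed cell
tower (MAC-tower).  City coordinates follow the masking convention used
when operator data must stay de-identified: each city carries the latitude
of the center of a latitudinal band and a longitude *relative* to an
arbitrary reference point inside that band.

Timestamps are kept in official zone clock time throughout; conversion to
solar quantities happens only in :mod:`urbanrhythm.solar`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: Residence rule thresholds (km): tower-center, postal-center, tower-postal.
MAX_TOWER_CENTER_KM = 15.0
MAX_POSTAL_CENTER_KM = 15.0
MAX_TOWER_POSTAL_KM = 30.0

#: Minimum population for a city to enter the study (strictly greater-than).
DEFAULT_MIN_POPULATION = 100_000

CDR_COLUMNS = ["caller_id", "callee_id", "start", "duration_s"]
SUBSCRIBER_COLUMNS = [
    "id", "age", "gender", "postal_lat", "postal_lon",
    "tower_lat", "tower_lon", "home_city",
]
CITY_COLUMNS = [
    "id", "band_latitude", "band_halfwidth", "rel_longitude",
    "population", "center_lat", "center_lon",
]


@dataclass(frozen=True)
class CallRecord:
    """One outgoing call event."""

    caller_id: str
    callee_id: str
    start: pd.Timestamp
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError(f"negative call duration: {self.duration_s}")


@dataclass(frozen=True)
class SubscriberInfo:
    """Demographics and residence proxies for one subscriber."""

    id: str
    age: int | None
    gender: str  # "female" | "male" | "unknown"
    postal_centroid: tuple[float, float] | None
    mac_tower: tuple[float, float] | None
    home_city: str | None = None

    def __post_init__(self) -> None:
        if self.age is not None and not (0 <= self.age <= 120):
            raise ValueError(f"age out of range: {self.age}")
        for coords in (self.postal_centroid, self.mac_tower):
            if coords is not None:
                _validate_coords(*coords)


@dataclass(frozen=True)
class City:
    """A city under the coordinate-masking convention.

    ``band_latitude`` is the center latitude of the city's band (degrees),
    ``rel_longitude`` the signed angular offset from the band's reference
    point (west negative).  ``center`` is the unmasked point used only for
    the residence distance rules.
    """

    id: str
    band_latitude: float
    band_halfwidth: float
    rel_longitude: float
    population: int
    center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.band_halfwidth <= 0:
            raise ValueError("band_halfwidth must be positive")
        if self.population <= 0:
            raise ValueError("population must be positive")
        _validate_coords(*self.center)


@dataclass
class LatitudinalBand:
    """A set of cities compared at (approximately) common latitude."""

    center_latitude: float
    halfwidth: float
    member_city_ids: list[str]
    reference_city_id: str

    def __post_init__(self) -> None:
        if self.reference_city_id not in self.member_city_ids:
            raise ValueError(
                f"reference city {self.reference_city_id!r} is not a band member"
            )

    def validate_members(self, cities: dict[str, City]) -> None:
        lo = self.center_latitude - self.halfwidth
        hi = self.center_latitude + self.halfwidth
        for cid in self.member_city_ids:
            lat = cities[cid].band_latitude
            if not (lo <= lat <= hi):
                raise ValueError(
                    f"city {cid!r} latitude {lat} outside band "
                    f"[{lo}, {hi}]"
                )


@dataclass
class ReadResult:
    """Parsed records plus a count of malformed rows that were skipped."""

    records: list[CallRecord] = field(default_factory=list)
    n_skipped: int = 0


def _validate_coords(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude out of range: {lat}")
    if not (-180.0 <= lon <= 180.0):
        raise ValueError(f"longitude out of range: {lon}")


def haversine_km(a: Sequence[float], b: Sequence[float]) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees.

    Uses the haversine formula on a sphere of radius 6371 km; symmetric and
    non-negative.
    """
    _validate_coords(*a)
    _validate_coords(*b)
    lat1, lon1, lat2, lon2 = map(np.radians, (a[0], a[1], b[0], b[1]))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def resides_in_city(sub: SubscriberInfo, city: City) -> bool:
    """Whether a subscriber's residence proxies place them in ``city``.

    All three rules must hold, each with a strict inequality:
    tower-to-center < 15 km, postal-to-center < 15 km, and
    tower-to-postal < 30 km.  Missing coordinates fail the check (logged),
    they do not raise.
    """
    if sub.mac_tower is None or sub.postal_centroid is None:
        logger.info("subscriber %s excluded: missing coordinates", sub.id)
        return False
    return (
        haversine_km(sub.mac_tower, city.center) < MAX_TOWER_CENTER_KM
        and haversine_km(sub.postal_centroid, city.center) < MAX_POSTAL_CENTER_KM
        and haversine_km(sub.mac_tower, sub.postal_centroid) < MAX_TOWER_POSTAL_KM
    )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def read_cdr(path, timestamp_format: str | None = None,
             columns: dict[str, str] | None = None) -> ReadResult:
    """Read a CDR CSV into :class:`CallRecord` objects, skipping bad rows.

    Parameters
    ----------
    path:
        CSV file with a header row.
    timestamp_format:
        Optional ``strftime`` pattern for the start column; by default
        ISO-8601 is assumed.
    columns:
        Optional mapping from the canonical names
        (``caller_id, callee_id, start, duration_s``) to the file's column
        names, for non-default schemas.

    Row order is preserved; rows with an unparsable timestamp or a negative
    or non-numeric duration are counted in ``n_skipped`` and dropped.
    """
    colmap = {c: c for c in CDR_COLUMNS}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"CDR file {path} is missing mandatory column(s): {missing}")

    start = pd.to_datetime(
        df[colmap["start"]], format=timestamp_format, errors="coerce"
    )
    duration = pd.to_numeric(df[colmap["duration_s"]], errors="coerce")
    ok = start.notna() & duration.notna() & (duration >= 0)

    result = ReadResult(n_skipped=int((~ok).sum()))
    for caller, callee, ts, dur in zip(
        df.loc[ok, colmap["caller_id"]],
        df.loc[ok, colmap["callee_id"]],
        start[ok],
        duration[ok],
    ):
        result.records.append(CallRecord(caller, callee, ts, float(dur)))
    return result


def read_cdr_frame(path, timestamp_format: str | None = None) -> pd.DataFrame:
    """Read a CDR CSV as a DataFrame (pipeline fast path).

    Same skipping semantics as :func:`read_cdr`; the skip count is logged
    rather than returned.
    """
    df = pd.read_csv(path, dtype={"caller_id": str, "callee_id": str})
    missing = [c for c in CDR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CDR file {path} is missing mandatory column(s): {missing}")
    df["start"] = pd.to_datetime(df["start"], format=timestamp_format, errors="coerce")
    df["duration_s"] = pd.to_numeric(df["duration_s"], errors="coerce")
    ok = df["start"].notna() & df["duration_s"].notna() & (df["duration_s"] >= 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("%s: skipped %d malformed CDR rows", path, n_skipped)
    return df[ok].reset_index(drop=True)


def write_cdr(path, records: Iterable[CallRecord]) -> None:
    df = pd.DataFrame(
        [
            {
                "caller_id": r.caller_id,
                "callee_id": r.callee_id,
                "start": r.start.isoformat(),
                "duration_s": r.duration_s,
            }
            for r in records
        ],
        columns=CDR_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_subscribers(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "home_city": str})
    missing = [c for c in SUBSCRIBER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subscriber file {path} missing column(s): {missing}")
    return df


def read_cities(path) -> list[City]:
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in CITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cities file {path} missing column(s): {missing}")
    return [
        City(
            id=row.id,
            band_latitude=float(row.band_latitude),
            band_halfwidth=float(row.band_halfwidth),
            rel_longitude=float(row.rel_longitude),
            population=int(row.population),
            center=(float(row.center_lat), float(row.center_lon)),
        )
        for row in df.itertuples(index=False)
    ]


def write_cities(path, cities: Iterable[City]) -> None:
    pd.DataFrame(
        [
            {
                "id": c.id,
                "band_latitude": c.band_latitude,
                "band_halfwidth": c.band_halfwidth,
                "rel_longitude": c.rel_longitude,
                "population": c.population,
                "center_lat": c.center[0],
                "center_lon": c.center[1],
            }
            for c in cities
        ],
        columns=CITY_COLUMNS,
    ).to_csv(path, index=False)


def subscriber_from_row(row) -> SubscriberInfo:
    """Build a :class:`SubscriberInfo` from one subscriber-table row."""
    def _pair(lat, lon):
        if pd.isna(lat) or pd.isna(lon):
            return None
        return (float(lat), float(lon))

    age = None if pd.isna(row.age) else int(row.age)
    gender = row.gender if row.gender in ("female", "male") else "unknown"
    home = None if (pd.isna(row.home_city) or row.home_city == "") else str(row.home_city)
    return SubscriberInfo(
        id=str(row.id),
        age=age,
        gender=gender,
        postal_centroid=_pair(row.postal_lat, row.postal_lon),
        mac_tower=_pair(row.tower_lat, row.tower_lon),
        home_city=home,
    )


def filter_study_population(
    subscribers: pd.DataFrame,
    cities: Sequence[City],
    min_population: int = DEFAULT_MIN_POPULATION,
) -> pd.Series:
    """Assign subscribers to their declared home city where residence holds.

    Only cities with population strictly greater than ``min_population``
    are retained.  A subscriber is assigned to its declared ``home_city``
    iff that city survives the population cut and all three residence
    distance rules pass; everyone else is left unassigned.

    Returns a Series indexed by subscriber id mapping to a city id.
    """
    eligible = {c.id: c for c in cities if c.population > min_population}
    assigned: dict[str, str] = {}
    for row in subscribers.itertuples(index=False):
        sub = subscriber_from_row(row)
        if sub.home_city is None or sub.home_city not in eligible:
            continue
        if resides_in_city(sub, eligible[sub.home_city]):
            assigned[sub.id] = sub.home_city
    return pd.Series(assigned, name="city", dtype=str)
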