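"""Fix-table I/O, date arithmetic and great-circle geometry shared by all stages.

The unit of raw data is the Argos Doppler fix: an animal id, a UTC
timestamp, a WGS84 latitude/longitude and a location class (LC) in
{3, 2, 1, 0, A, B, Z}.  Classes 3..0 carry nominal 1-sigma error radii
(150 m up to >1 km); A, B and Z carry no accuracy estimate.  Fixes are
grouped into time-ordered :class:`Track` objects, one per animal.

All date arithmetic for the statistics layer uses a *non-leap*
day-of-year convention: every year is treated as 365 days and Feb 29 is
collapsed onto day 59 (same as Feb 28).  Cross-year durations are
``(365 - doy_start) + doy_end``.  Distances are great-circle
(haversine) on a sphere of radius 6371.0 km.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven-value Argos location-class alphabet.
LC_ALPHABET = ("3", "2", "1", "0", "A", "B", "Z")

#: Accuracy ordering used by the filter: Z worst, 3 best.
LC_RANK = {"Z": 0, "B": 1, "A": 2, "0": 3, "1": 4, "2": 5, "3": 6}

EARTH_RADIUS_KM = 6371.0

_CUM_DAYS = (0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334)
_MONTH_LEN = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)

_UTC = dt.timezone.utc


class SchemaError(ValueError):
    """A fix table is missing a required column."""


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ArgosFix:
    """One Doppler location with timestamp and accuracy class."""

    animal_id: str
    timestamp: dt.datetime
    lat: float
    lon: float
    lc: str

    def __post_init__(self) -> None:
        if self.lc not in LC_ALPHABET:
            raise ValueError(f"location class {self.lc!r} not in {LC_ALPHABET}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of [-180, 180]")
        ts = self.timestamp
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=_UTC)
        else:
            ts = ts.astimezone(_UTC)
        object.__setattr__(self, "timestamp", ts)


@dataclasses.dataclass(frozen=True)
class DeploymentMeta:
    """Transmitter duty cycle and capture context for one deployment."""

    duty_on_hours: float
    duty_off_hours: float
    capture_lat: float
    capture_lon: float
    year: int

    def __post_init__(self) -> None:
        if self.duty_on_hours <= 0:
            raise ValueError("duty_on_hours must be > 0")
        if self.duty_off_hours < 0:
            raise ValueError("duty_off_hours must be >= 0")


class Track:
    """A time-ordered sequence of fixes for one animal.

    Internally stored as parallel numpy arrays (epoch seconds, lat, lon,
    lc) for speed; :class:`ArgosFix` views are built on demand.
    """

    __slots__ = ("animal_id", "t", "lat", "lon", "lc", "deployment", "_fixes")

    def __init__(self, animal_id: str, t: np.ndarray, lat: np.ndarray,
                 lon: np.ndarray, lc: np.ndarray,
                 deployment: DeploymentMeta | None = None) -> None:
        t = np.asarray(t, dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError("fix timestamps must be non-decreasing")
        self.animal_id = str(animal_id)
        self.t = t
        self.lat = np.asarray(lat, dtype=float)
        self.lon = np.asarray(lon, dtype=float)
        self.lc = np.asarray(lc, dtype=object)
        if not (len(t) == len(self.lat) == len(self.lon) == len(self.lc)):
            raise ValueError("field arrays must have equal length")
        self.deployment = deployment
        self._fixes: tuple[ArgosFix, ...] | None = None

    @classmethod
    def from_fixes(cls, fixes: Sequence[ArgosFix],
                   deployment: DeploymentMeta | None = None) -> "Track":
        if not fixes:
            raise ValueError("a Track needs at least one fix")
        ids = {f.animal_id for f in fixes}
        if len(ids) != 1:
            raise ValueError(f"fixes span multiple animal ids: {sorted(ids)}")
        fixes = sorted(fixes, key=lambda f: f.timestamp)
        return cls(
            fixes[0].animal_id,
            np.array([f.timestamp.timestamp() for f in fixes]),
            np.array([f.lat for f in fixes]),
            np.array([f.lon for f in fixes]),
            np.array([f.lc for f in fixes], dtype=object),
            deployment,
        )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n(self) -> int:
        return len(self.t)

    def fix(self, i: int) -> ArgosFix:
        return ArgosFix(self.animal_id, epoch_to_datetime(self.t[i]),
                        float(self.lat[i]), float(self.lon[i]), str(self.lc[i]))

    @property
    def fixes(self) -> tuple[ArgosFix, ...]:
        if self._fixes is None:
            self._fixes = tuple(self.fix(i) for i in range(len(self)))
        return self._fixes

    def __iter__(self) -> Iterator[ArgosFix]:
        return iter(self.fixes)

    def subset(self, index: np.ndarray) -> "Track":
        """A new Track restricted to the given (sorted) integer/boolean index."""
        return Track(self.animal_id, self.t[index], self.lat[index],
                     self.lon[index], self.lc[index], self.deployment)

    def lc_rank(self) -> np.ndarray:
        return np.array([LC_RANK[c] for c in self.lc], dtype=int)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Track {self.animal_id}: {len(self)} fixes>"


def epoch_to_datetime(t: float) -> dt.datetime:
    return dt.datetime.fromtimestamp(float(t), tz=_UTC)


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _check_coord(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValueError(f"coordinate ({lat}, {lon}) out of range")


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) pairs.

    Symmetric, non-negative and zero iff the points coincide; sphere
    radius fixed at 6371.0 km.
    """
    _check_coord(*a)
    _check_coord(*b)
    return float(_haversine_arr(np.array(a[0]), np.array(a[1]),
                                np.array(b[0]), np.array(b[1])))


def _haversine_arr(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Vectorised haversine (degrees in, km out); no range validation."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def step_distances_km(track: Track) -> np.ndarray:
    """Distances between consecutive fixes of a track (length n-1)."""
    return _haversine_arr(track.lat[:-1], track.lon[:-1],
                          track.lat[1:], track.lon[1:])


# --------------------------------------------------------------------------
# non-leap calendar arithmetic
# --------------------------------------------------------------------------

def day_of_year_nonleap(date: dt.date | dt.datetime) -> int:
    """Day of year in [1, 365] with every year treated as non-leap.

    Feb 29 maps to 59, the same day as Feb 28, so dates from leap and
    non-leap years are directly comparable.
    """
    if isinstance(date, dt.datetime):
        date = date.date()
    day = min(date.day, _MONTH_LEN[date.month - 1])
    return _CUM_DAYS[date.month - 1] + day


def date_from_nonleap_doy(doy: float, year: int = 2001) -> dt.date:
    """Inverse of :func:`day_of_year_nonleap` (doy rounded to nearest day)."""
    d = int(round(doy))
    if not 1 <= d <= 365:
        raise ValueError(f"day of year {doy} out of [1, 365]")
    month = max(i for i, c in enumerate(_CUM_DAYS) if c < d) + 1
    return dt.date(year, month, d - _CUM_DAYS[month - 1])


def nonleap_days_between(start: dt.date, end: dt.date) -> int:
    """Signed day count from start to end under the non-leap convention.

    Within one calendar year this is the plain day-of-year difference;
    across years each elapsed year contributes exactly 365 days, which
    implements the cross-year rule ``(365 - doy_start) + doy_end``.
    """
    return (end.year - start.year) * 365 + (
        day_of_year_nonleap(end) - day_of_year_nonleap(start))


# --------------------------------------------------------------------------
# delimited fix tables
# --------------------------------------------------------------------------

REQUIRED_COLUMNS = ("animal_id", "timestamp", "lat", "lon", "lc")


@dataclasses.dataclass
class ReadReport:
    """Row accounting for one :func:`read_fixes` call."""

    n_rows: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    reasons: Counter = dataclasses.field(default_factory=Counter)


def read_fixes(path: str | Path, dialect: Mapping[str, str] | None = None,
               delimiter: str = ",",
               report: ReadReport | None = None) -> list[Track]:
    """Read a delimited fix table into one :class:`Track` per animal.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Optional mapping from the required column names
        (``animal_id, timestamp, lat, lon, lc``) to the names actually
        used in the file.
    delimiter
        Field separator (default comma; pass ``"\\t"`` for tab).
    report
        Optional :class:`ReadReport` that is filled with row counts and
        per-reason rejection tallies.

    Malformed rows (unparseable timestamp or coordinate, out-of-range
    coordinate, unknown location class) are rejected individually and
    logged; a missing column raises :class:`SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dict(dialect or {})
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    colmap = {std: dialect.get(std, std) for std in REQUIRED_COLUMNS}
    missing = [c for c in colmap.values() if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    ts = pd.to_datetime(frame[colmap["timestamp"]], errors="coerce",
                        utc=True, format="ISO8601")
    lat = pd.to_numeric(frame[colmap["lat"]], errors="coerce")
    lon = pd.to_numeric(frame[colmap["lon"]], errors="coerce")
    lc = frame[colmap["lc"]].astype(str).str.strip()

    bad_ts = ts.isna()
    bad_coord = lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 180)
    bad_lc = ~lc.isin(LC_ALPHABET)
    bad = bad_ts | bad_coord | bad_lc

    rep = report if report is not None else ReadReport()
    rep.n_rows = len(frame)
    rep.n_rejected = int(bad.sum())
    rep.n_kept = rep.n_rows - rep.n_rejected
    rep.reasons.update({
        "timestamp": int(bad_ts.sum()),
        "coordinate": int((bad_coord & ~bad_ts).sum()),
        "lc": int((bad_lc & ~bad_ts & ~bad_coord).sum()),
    })
    if rep.n_rejected:
        logger.warning("read_fixes: rejected %d of %d rows (%s)",
                       rep.n_rejected, rep.n_rows,
                       {k: v for k, v in rep.reasons.items() if v})

    keep = frame[~bad]
    tracks = []
    for animal, grp in keep.groupby(colmap["animal_id"], sort=True):
        order = np.argsort(ts[grp.index].values, kind="stable")
        idx = grp.index[order]
        tracks.append(Track(
            str(animal),
            ts[idx].astype("int64").to_numpy() / 1e9,
            lat[idx].to_numpy(),
            lon[idx].to_numpy(),
            lc[idx].to_numpy(dtype=object),
        ))
    return tracks


def write_fixes(tracks: Iterable[Track], path: str | Path,
                delimiter: str = ",") -> None:
    """Write tracks back to a delimited fix table (ISO 8601 timestamps)."""
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            rows.append((tr.animal_id,
                         epoch_to_datetime(tr.t[i]).isoformat(),
                         repr(float(tr.lat[i])), repr(float(tr.lon[i])),
                         str(tr.lc[i])))
    frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    frame.to_csv(path, sep=delimiter, index=False)


# --------------------------------------------------------------------------
# packaged fixtures (reference journey and stopover-site tables)
# --------------------------------------------------------------------------

#: SHA-256 of the packaged reference tables; loading fails on mismatch.
_TABLE1_SHA256 = "f640c86a210937f565db5aad0da4f5df92ee39969b8d3648f25c359dc0b4fc9b"
_TABLE4_SHA256 = "c1c08ea3a8bba183bdc9008c38946224fe58c31875c9b984c5b05cad6cd1200e"


@dataclasses.dataclass(frozen=True)
class JourneyRecord:
    """One seasonal migration journey in tabular (fixture) form."""

    individual: str
    season: str           # "autumn" | "spring"
    year: int             # calendar year of departure
    departure: dt.date
    arrival: dt.date
    n_stopovers: int
    segment_lengths_km: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.season not in ("autumn", "spring"):
            raise ValueError(f"season {self.season!r}")
        if len(self.segment_lengths_km) != self.n_stopovers + 1:
            raise ValueError("need n_stopovers + 1 segment lengths")

    @property
    def total_km(self) -> float:
        return float(sum(self.segment_lengths_km))

    @property
    def departure_doy(self) -> int:
        return day_of_year_nonleap(self.departure)

    @property
    def arrival_doy(self) -> int:
        return day_of_year_nonleap(self.arrival)

    @property
    def duration_days(self) -> int:
        return nonleap_days_between(self.departure, self.arrival)


def _packaged(name: str, expected_sha: str) -> str:
    data = resources.files("relicttrack.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != expected_sha:
        raise FixtureIntegrityError(
            f"checksum mismatch for packaged fixture {name}: {digest}")
    return data.decode("utf-8")


def load_table1_fixture() -> list[JourneyRecord]:
    """The packaged reference journey table (satellite-tracked Relict
    Gulls, Hongjian Nur, 2008-2012): 20 complete autumn and 13 complete
    spring journeys with departure/arrival dates, stopover counts and
    per-segment great-circle lengths."""
    import io
    text = _packaged("table1_journeys.csv", _TABLE1_SHA256)
    frame = pd.read_csv(io.StringIO(text), dtype=str)
    records = []
    for row in frame.itertuples(index=False):
        records.append(JourneyRecord(
            individual=row.individual,
            season=row.season,
            year=int(row.year),
            departure=dt.date.fromisoformat(row.departure),
            arrival=dt.date.fromisoformat(row.arrival),
            n_stopovers=int(row.n_stopovers),
            segment_lengths_km=tuple(
                float(s) for s in row.segments_km.split("/")),
        ))
    return records


def load_table4_sites() -> pd.DataFrame:
    """The packaged reference stopover-site table: named sites with
    coordinates, stopover frequency (journeys) and accumulated days."""
    import io
    text = _packaged("table4_sites.csv", _TABLE4_SHA256)
    return pd.read_csv(io.StringIO(text))


# --------------------------------------------------------------------------
# GeoJSON output
# --------------------------------------------------------------------------

def tracks_to_geojson(tracks: Iterable[Track]) -> dict:
    """A FeatureCollection with one LineString per animal."""
    features = []
    for tr in tracks:
        coords = [[round(float(x), 6), round(float(y), 6)]
                  for x, y in zip(tr.lon, tr.lat)]
        features.append({
            "type": "Feature",
            "properties": {"animal_id": tr.animal_id, "n_fixes": len(tr)},
            "geometry": {"type": "LineString", "coordinates": coords},
        })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_geojson(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
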