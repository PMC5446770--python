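"""Wintering-ground residence, between-bay dispersal and pre-breeding
excursions.

Regions are named polygons (GeoJSON) or discs; a fix on a polygon
boundary counts as inside.  A change of occupied region only counts as
a dispersal event if the new occupancy persists for at least 24 h,
which suppresses duty-cycle flicker at region boundaries.  Pre-breeding
dispersal is an excursion from the breeding colony whose maximum
displacement reaches ``min_km`` (default 100 km, the minimum of the
observed excursion range) and lasts at least 24 h.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path

import numpy as np
import shapely

from .segmentation import MigrationEvent, event_date
from .track_io import (Track, _haversine_arr, day_of_year_nonleap,
                       epoch_to_datetime, read_geojson)


class Region:
    """A named region against which fixes are classified."""

    name: str

    def contains(self, lat: float, lon: float) -> bool:
        return bool(self.contains_many(np.array([lat]), np.array([lon]))[0])

    def contains_many(self, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class PolygonRegion(Region):
    """A polygon/multipolygon region; boundary points count as inside."""

    def __init__(self, name: str, geometry) -> None:
        self.name = name
        self.geometry = shapely.make_valid(shapely.geometry.shape(geometry)
                                           if isinstance(geometry, dict)
                                           else geometry)
        shapely.prepare(self.geometry)

    def contains_many(self, lats, lons) -> np.ndarray:
        return shapely.intersects_xy(self.geometry, np.asarray(lons),
                                     np.asarray(lats))


class DiscRegion(Region):
    """A great-circle disc of ``radius_km`` around a centre point."""

    def __init__(self, name: str, center: tuple[float, float],
                 radius_km: float) -> None:
        self.name = name
        self.center = (float(center[0]), float(center[1]))
        self.radius_km = float(radius_km)

    def contains_many(self, lats, lons) -> np.ndarray:
        d = _haversine_arr(np.asarray(lats), np.asarray(lons),
                           self.center[0], self.center[1])
        return d <= self.radius_km


def load_regions(path: str | Path | None = None) -> list[Region]:
    """Load named regions from a GeoJSON FeatureCollection.

    Point features with a ``radius_km`` property become discs; Polygon
    and MultiPolygon features become polygon regions.  With no path the
    packaged *synthetic* region file is used (approximate hand-drawn
    bay rectangles around the published wintering grounds plus the
    published colony location).
    """
    if path is None:
        from importlib import resources
        import json
        obj = json.loads(resources.files("relicttrack.data")
                         .joinpath("synthetic_regions.geojson").read_text())
    else:
        obj = read_geojson(path)
    regions: list[Region] = []
    for feat in obj["features"]:
        props = feat.get("properties", {})
        name = props.get("name", f"region_{len(regions)}")
        geom = feat["geometry"]
        if geom["type"] == "Point":
            lon, lat = geom["coordinates"]
            regions.append(DiscRegion(name, (lat, lon),
                                      float(props.get("radius_km", 20.0))))
        else:
            regions.append(PolygonRegion(name, geom))
    return regions


@dataclasses.dataclass(frozen=True)
class DispersalEvent:
    """A change of occupied region (winter) or a colony excursion
    (pre-breeding)."""

    from_region: str
    to_region: str
    date: MigrationEvent
    kind: str                       # "winter" | "pre_breeding"
    excursion_km: float | None = None
    duration_days: float | None = None
    open_ended: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("winter", "pre_breeding"):
            raise ValueError(f"kind {self.kind!r}")
        if self.kind == "winter" and self.from_region == self.to_region:
            raise ValueError("winter dispersal requires from != to")


def classify_region(fix, regions) -> str | None:
    """Name of the first region (in input order) containing the fix,
    or None.  ``fix`` may be an ArgosFix or a (lat, lon) pair."""
    lat, lon = (fix.lat, fix.lon) if hasattr(fix, "lat") else fix
    for reg in regions:
        if reg.contains(lat, lon):
            return reg.name
    return None


def _occupancy_runs(names: np.ndarray, t: np.ndarray,
                    min_hours: float = 24.0) -> list[tuple[str, int, int]]:
    runs: list[tuple[str, int, int]] = []
    for i, s in enumerate(names):
        if s is None:
            continue
        if runs and runs[-1][0] == s and all(
                names[j] is None for j in range(runs[-1][2] + 1, i)):
            runs[-1] = (s, runs[-1][1], i)
        else:
            runs.append((s, i, i))
    keep = [r for r in runs if (t[r[2]] - t[r[1]]) / 3600.0 >= min_hours]
    collapsed: list[tuple[str, int, int]] = []
    for r in keep:
        if collapsed and collapsed[-1][0] == r[0]:
            collapsed[-1] = (r[0], collapsed[-1][1], r[2])
        else:
            collapsed.append(r)
    return collapsed


def detect_winter_dispersal(track: Track, regions,
                            start: dt.datetime | None = None,
                            end: dt.datetime | None = None,
                            min_hours: float = 24.0) -> list[DispersalEvent]:
    """Dispersal events between named regions within a wintering window.

    Each change of occupied region that persists at least ``min_hours``
    yields one event, dated by the median-instant rule on the bracketing
    fixes.  ``start``/``end`` (e.g. the winter arrival and spring
    departure events) restrict the fixes considered.
    """
    mask = np.ones(len(track), dtype=bool)
    if start is not None:
        mask &= track.t >= start.timestamp()
    if end is not None:
        mask &= track.t <= end.timestamp()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = track.subset(idx)

    names = np.empty(len(sub), dtype=object)
    names[:] = None
    for reg in regions:
        hit = reg.contains_many(sub.lat, sub.lon) & (names == None)  # noqa: E711
        names[hit] = reg.name

    runs = _occupancy_runs(names, sub.t, min_hours=min_hours)
    events = []
    for (na, a0, a1), (nb, b0, b1) in zip(runs, runs[1:]):
        events.append(DispersalEvent(
            from_region=na, to_region=nb,
            date=event_date(epoch_to_datetime(sub.t[a1]),
                            epoch_to_datetime(sub.t[b0])),
            kind="winter",
        ))
    return events


def detect_prebreeding_dispersal(track: Track, colony: tuple[float, float],
                                 min_km: float = 100.0,
                                 colony_radius_km: float = 20.0,
                                 after: dt.datetime | None = None,
                                 min_hours: float = 24.0) -> list[DispersalEvent]:
    """Excursions away from the breeding colony after spring arrival.

    An excursion is a maximal run of fixes outside the colony disc.  It
    is reported if it lasts at least ``min_hours`` and its maximum
    great-circle displacement from the colony reaches ``min_km``;
    ``duration_days`` runs from the last fix inside the colony to the
    first fix back inside (to the end of the track, flagged
    ``open_ended``, if the bird never returns).
    """
    mask = np.ones(len(track), dtype=bool)
    if after is not None:
        mask &= track.t >= after.timestamp()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = track.subset(idx)
    disp = _haversine_arr(sub.lat, sub.lon, colony[0], colony[1])
    outside = disp > colony_radius_km

    events = []
    i = 0
    n = len(sub)
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and outside[j + 1]:
            j += 1
        span_h = (sub.t[j] - sub.t[i]) / 3600.0
        peak = float(np.max(disp[i:j + 1]))
        if span_h >= min_hours and peak >= min_km:
            last_in = i - 1
            first_back = j + 1 if j + 1 < n else None
            t0 = sub.t[last_in] if last_in >= 0 else sub.t[i]
            t1 = sub.t[first_back] if first_back is not None else sub.t[j]
            events.append(DispersalEvent(
                from_region="colony", to_region="colony",
                date=event_date(epoch_to_datetime(t0),
                                epoch_to_datetime(sub.t[i])),
                kind="pre_breeding",
                excursion_km=peak,
                duration_days=float((t1 - t0) / 86400.0),
                open_ended=first_back is None,
            ))
        i = j + 1
    return events


def residence_duration(arrival: dt.date, departure: dt.date) -> int:
    """Days of residence between an arrival and the next departure
    under the non-leap convention; cross-year residences count
    ``(365 - doy_arrival) + doy_departure``."""
    d = (departure.year - arrival.year) * 365 + (
        day_of_year_nonleap(departure) - day_of_year_nonleap(arrival))
    if d < 0:
        raise ValueError("departure precedes arrival")
    return d
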