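"""Stopover detection, migration-event dating and journey delineation.

A stopover is an interval in which the bird moved less than a threshold
radius (default 20 km) for at least a minimum duration (default 24 h):
a greedy left-to-right window grows while every member fix lies within
the radius of the running centroid.  Because transmitters duty-cycle,
departure/arrival events are dated by the median instant between the
last fix at the previous location and the first fix at the new one;
events bridging a gap of more than ten days are left undated.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging

import numpy as np

from .track_io import (Track, _haversine_arr, epoch_to_datetime,
                       haversine_km, nonleap_days_between)

logger = logging.getLogger(__name__)

#: Events bridging a sampling gap longer than this are not dated.
MAX_EVENT_GAP_DAYS = 10.0


@dataclasses.dataclass(frozen=True)
class Stopover:
    """A bounded residence cluster with centroid and duration.

    ``member_ranges`` holds the (first, last) fix-index ranges of the
    member fixes in the source track; a merged stopover carries one
    range per merged cluster (fixes falling between clusters are not
    members).
    """

    centroid: tuple[float, float]      # (lat, lon)
    start: dt.datetime
    end: dt.datetime
    duration_days: float
    n_fixes: int
    member_ranges: tuple = ()

    def member_indices(self) -> np.ndarray:
        return np.concatenate([np.arange(a, b + 1)
                               for a, b in self.member_ranges])

    def max_member_distance_km(self, lats, lons) -> float:
        d = _haversine_arr(np.asarray(lats), np.asarray(lons),
                           self.centroid[0], self.centroid[1])
        return float(np.max(d))


@dataclasses.dataclass(frozen=True)
class MigrationEvent:
    """A departure or arrival, dated by the median-instant rule.

    ``date`` is None iff the bracketing sampling gap exceeds
    :data:`MAX_EVENT_GAP_DAYS`.
    """

    date: dt.date | None
    gap_days: float


@dataclasses.dataclass
class Journey:
    """One seasonal migration between residence regions."""

    individual: str
    season: str                       # "autumn" | "spring"
    year: int
    departure: MigrationEvent
    arrival: MigrationEvent
    stopovers: tuple[Stopover, ...]
    segment_lengths_km: tuple[float, ...]

    @property
    def total_km(self) -> float:
        return float(sum(self.segment_lengths_km))

    @property
    def n_stopovers(self) -> int:
        return len(self.stopovers)

    @property
    def duration_days(self) -> int | None:
        if self.departure.date is None or self.arrival.date is None:
            return None
        return nonleap_days_between(self.departure.date, self.arrival.date)


@dataclasses.dataclass(frozen=True)
class RouteMetrics:
    """End-to-end longitudinal/latitudinal spans and the latitude at
    which a reference meridian is first crossed."""

    delta_lon: float
    delta_lat: float
    lat_at_meridian: float | None


# --------------------------------------------------------------------------
# stopovers
# --------------------------------------------------------------------------

def detect_stopovers(track: Track, radius_km: float = 20.0,
                     min_hours: float = 24.0) -> list[Stopover]:
    """Greedy residence clustering of a time-ordered track.

    A window grows while every fix lies within ``radius_km`` of the
    running centroid (arithmetic mean of member coordinates); windows
    spanning at least ``min_hours`` with >= 2 fixes emit a
    :class:`Stopover`.  Consecutive stopovers whose centroids lie
    within ``radius_km`` of each other and whose time gap is <= 24 h
    are merged.  Emitted stopovers are disjoint in time and ordered.
    """
    n = len(track)
    if n < 2:
        return []
    lat, lon, t = track.lat, track.lon, track.t
    raw: list[tuple[int, int]] = []   # [start, end] member index ranges

    s = 0
    while s < n - 1:
        # grow [s..j]; incremental centroid with lazy full re-verification
        cx, cy = lat[s], lon[s]
        ref_x, ref_y = cx, cy          # centroid at last full check
        verified_max = 0.0             # max member dist at that check
        j = s
        while j + 1 < n:
            k = j + 1
            m = k - s + 1
            nx = cx + (lat[k] - cx) / m
            ny = cy + (lon[k] - cy) / m
            if haversine_km((float(lat[k]), float(lon[k])),
                            (float(nx), float(ny))) > radius_km:
                break
            cx, cy, j = nx, ny, k
            drift = haversine_km((float(cx), float(cy)),
                                 (float(ref_x), float(ref_y)))
            if verified_max + drift > radius_km:
                d = _haversine_arr(lat[s:j + 1], lon[s:j + 1], cx, cy)
                if float(np.max(d)) > radius_km:
                    j -= 1
                    cx = float(np.mean(lat[s:j + 1]))
                    cy = float(np.mean(lon[s:j + 1]))
                    break
                ref_x, ref_y, verified_max = cx, cy, float(np.max(d))
        span_h = (t[j] - t[s]) / 3600.0
        if span_h >= min_hours and j > s:
            raw.append((s, j))
            s = j + 1
        else:
            s += 1

    def _centroid(ranges):
        idx = np.concatenate([np.arange(a, b + 1) for a, b in ranges])
        return (float(np.mean(lat[idx])), float(np.mean(lon[idx])))

    def _fits(ranges) -> bool:
        cx, cy = _centroid(ranges)
        idx = np.concatenate([np.arange(ra, rb + 1) for ra, rb in ranges])
        return float(np.max(_haversine_arr(lat[idx], lon[idx], cx, cy))) <= radius_km

    merged: list[list[tuple[int, int]]] = []
    for (a, b) in raw:
        if merged:
            pb = merged[-1][-1][1]
            gap_h = (t[a] - t[pb]) / 3600.0
            if (gap_h <= 24.0
                    and haversine_km(_centroid(merged[-1]),
                                     _centroid([(a, b)])) <= radius_km
                    and _fits(merged[-1] + [(a, b)])):
                merged[-1].append((a, b))
                continue
        merged.append([(a, b)])

    out = []
    for ranges in merged:
        a, b = ranges[0][0], ranges[-1][1]
        out.append(Stopover(
            centroid=_centroid(ranges),
            start=epoch_to_datetime(t[a]),
            end=epoch_to_datetime(t[b]),
            duration_days=float((t[b] - t[a]) / 86400.0),
            n_fixes=int(sum(rb - ra + 1 for ra, rb in ranges)),
            member_ranges=tuple(ranges),
        ))
    return out


# --------------------------------------------------------------------------
# event dating
# --------------------------------------------------------------------------

def event_date(last_prev: dt.datetime, first_new: dt.datetime) -> MigrationEvent:
    """Date a departure/arrival as the median instant between the last
    fix at the previous location and the first fix at the new one.

    If the gap exceeds ten days the event is left undated.  A midpoint
    falling exactly at midnight is assigned the earlier date.
    """
    if last_prev > first_new:
        raise ValueError("last_prev must not be after first_new")
    gap = first_new - last_prev
    gap_days = gap.total_seconds() / 86400.0
    if gap_days > MAX_EVENT_GAP_DAYS:
        return MigrationEvent(date=None, gap_days=gap_days)
    mid = last_prev + gap / 2
    date = mid.date()
    if mid.time() == dt.time(0, 0) and gap.total_seconds() > 0:
        date = date - dt.timedelta(days=1)
    return MigrationEvent(date=date, gap_days=gap_days)


# --------------------------------------------------------------------------
# journeys
# --------------------------------------------------------------------------

def _residence_visits(track: Track, membership: np.ndarray,
                      min_hours: float = 24.0) -> list[tuple[str, int, int]]:
    """Maximal runs of identical non-None region membership spanning at
    least ``min_hours`` (suppresses duty-cycle flicker at boundaries).
    Returns (state, first_index, last_index) triples, consecutive
    same-state visits collapsed."""
    visits: list[tuple[str, int, int]] = []
    cur: str | None = None
    start = 0
    idx = [i for i, s in enumerate(membership) if s is not None]
    for i in idx:
        s = membership[i]
        if cur is None or s != cur:
            cur, start = s, i
            visits.append((s, i, i))
        else:
            visits[-1] = (cur, start, i)
    keep = [v for v in visits
            if (track.t[v[2]] - track.t[v[1]]) / 3600.0 >= min_hours]
    collapsed: list[tuple[str, int, int]] = []
    for v in keep:
        if collapsed and collapsed[-1][0] == v[0]:
            collapsed[-1] = (v[0], collapsed[-1][1], v[2])
        else:
            collapsed.append(v)
    return collapsed


def delineate_journeys(track: Track, breeding_region, wintering_regions,
                       radius_km: float = 20.0,
                       stopovers: list[Stopover] | None = None) -> list[Journey]:
    """Split an annual (or multi-annual) track into seasonal journeys.

    ``breeding_region`` and each of ``wintering_regions`` must expose
    ``contains(lat, lon)`` (see :mod:`relicttrack.dispersal`).  The
    departure is dated between the last fix inside the origin residence
    region and the first subsequent fix; the arrival symmetrically at
    the destination.  Stopovers strictly between the two events are
    assigned to the journey, and segment lengths are great-circle
    distances origin -> stopover centroids -> destination, rounded to
    the nearest 10 km.
    """
    if stopovers is None:
        stopovers = detect_stopovers(track, radius_km=radius_km)
    wintering = list(wintering_regions)

    membership = np.empty(len(track), dtype=object)
    membership[:] = None
    b_mask = breeding_region.contains_many(track.lat, track.lon)
    membership[b_mask] = "B"
    w_mask = np.zeros(len(track), dtype=bool)
    for reg in wintering:
        w_mask |= reg.contains_many(track.lat, track.lon)
    membership[w_mask & ~b_mask] = "W"

    visits = _residence_visits(track, membership)
    if len(visits) < 2:
        logger.info("track %s: no residence transition found", track.animal_id)
        return []

    journeys = []
    for (sa, a0, a1), (sb, b0, b1) in zip(visits, visits[1:]):
        if sa == sb:
            continue
        season = "autumn" if sa == "B" else "spring"
        dep = event_date(epoch_to_datetime(track.t[a1]),
                         epoch_to_datetime(track.t[min(a1 + 1, len(track) - 1)]))
        arr = event_date(epoch_to_datetime(track.t[max(b0 - 1, 0)]),
                         epoch_to_datetime(track.t[b0]))
        t_dep, t_arr = track.t[a1], track.t[b0]
        mids = tuple(s for s in stopovers
                     if s.start.timestamp() > t_dep and s.end.timestamp() < t_arr)
        anchors = ([(float(track.lat[a1]), float(track.lon[a1]))]
                   + [s.centroid for s in mids]
                   + [(float(track.lat[b0]), float(track.lon[b0]))])
        segs = tuple(round(haversine_km(p, q) / 10.0) * 10.0
                     for p, q in zip(anchors, anchors[1:]))
        year = (dep.date or arr.date or epoch_to_datetime(t_dep).date()).year
        journeys.append(Journey(
            individual=track.animal_id, season=season, year=year,
            departure=dep, arrival=arr, stopovers=mids,
            segment_lengths_km=segs,
        ))
    return journeys


def route_metrics(track: Track, meridian_deg: float = 114.0) -> RouteMetrics:
    """Longitudinal/latitudinal spans of a journey track and the
    latitude of the first crossing of a reference meridian (linearly
    interpolated between the bracketing fixes)."""
    if len(track) < 2:
        raise ValueError("need >= 2 fixes")
    dlon = abs(float(track.lon[-1] - track.lon[0]))
    dlat = abs(float(track.lat[-1] - track.lat[0]))
    lat_x = None
    rel = track.lon - meridian_deg
    for i in range(len(track) - 1):
        a, b = rel[i], rel[i + 1]
        if a == 0.0:
            lat_x = float(track.lat[i])
            break
        if a * b < 0.0:
            f = a / (a - b)
            lat_x = float(track.lat[i] + f * (track.lat[i + 1] - track.lat[i]))
            break
    else:
        if len(rel) and rel[-1] == 0.0:
            lat_x = float(track.lat[-1])
    return RouteMetrics(delta_lon=dlon, delta_lat=dlat, lat_at_meridian=lat_x)
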