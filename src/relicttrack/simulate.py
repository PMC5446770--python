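"""Synthetic duty-cycled Argos tracks of an annual migratory cycle,
with exported ground truth.

The generator emulates the tracked system end to end: residence at the
breeding colony, autumn migration with 0-5 stopovers along a
northward-arched ("inverted V") or direct eastward route, months of
wintering residence with an optional mid-winter dispersal between two
coastal bays, a fast spring return, and an optional pre-breeding
excursion away from the colony.  The continuous truth trajectory is
sampled only during transmitter duty-on windows at hourly intervals;
each fix gets a location class drawn from a configured mix and an
isotropic Gaussian position error whose scale depends on the class.
A small fraction of auxiliary-class fixes are displaced 100-1000 km
and flagged as outliers in the ground truth.

Defaults follow the reference study conditions: colony at Hongjian Nur
(39.138 N, 109.870 E), wintering on the Bohai/Laizhou coast ~730 km to
the east, autumn departure around day 212 (31 Jul), spring departure
around day 95 (5 Apr), a 1.4-stopover mean, an 8 h on / 15 h off duty
cycle and ~41 % high-quality (LC 1-3) fixes.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math

import numpy as np

from . import argos_filter, segmentation
from .dispersal import DiscRegion, PolygonRegion, Region, load_regions
from .track_io import (EARTH_RADIUS_KM, Track, _haversine_arr,
                       epoch_to_datetime, haversine_km,
                       nonleap_days_between)

_UTC = dt.timezone.utc


class SimConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one simulated annual cycle."""

    seed: int = 0
    year: int = 2011
    colony: tuple[float, float] = (39.138, 109.870)
    winter_site_a: tuple[float, float] = (39.05, 118.30)   # Bohai coast
    winter_site_b: tuple[float, float] = (37.30, 119.00)   # Laizhou coast

    autumn_departure_doy_mean: float = 212.0   # ~31 Jul
    autumn_departure_doy_sd: float = 8.0
    spring_departure_doy_mean: float = 95.0    # ~5 Apr
    spring_departure_doy_sd: float = 3.0

    # stopover-count distributions on {0..5}
    n_stopovers_probs_autumn: tuple = (0.30, 0.25, 0.30, 0.10, 0.0, 0.05)
    n_stopovers_probs_spring: tuple = (10 / 13, 3 / 13, 0.0, 0.0, 0.0, 0.0)
    stopover_duration_min_days: float = 1.5
    stopover_duration_gamma: tuple[float, float] = (1.3, 5.0)  # shape, scale
    stopover_duration_max_days: float = 20.0
    inverted_v_prob: float = 13.0 / 20.0

    flight_speed_kmh: float = 40.0
    residence_radius_km: float = 10.0
    #: relaxation time of within-site movement (h); positions an hour
    #: apart at a residence site are strongly correlated, as in real
    #: telemetry, rather than independent draws
    residence_tau_hours: float = 12.0

    duty_on_hours: float = 8.0
    duty_off_hours: float = 15.0
    sample_interval_hours: float = 1.0

    lc_probs: dict = dataclasses.field(default_factory=lambda: {
        "3": 0.08, "2": 0.14, "1": 0.19, "0": 0.18, "A": 0.20, "B": 0.21})
    #: 1-sigma error radius per class, metres (RMS planar displacement)
    lc_sigma_m: dict = dataclasses.field(default_factory=lambda: {
        "3": 150.0, "2": 250.0, "1": 600.0, "0": 1200.0,
        "A": 3000.0, "B": 6000.0})
    outlier_rate: float = 0.02
    outlier_km_range: tuple[float, float] = (100.0, 1000.0)

    winter_dispersal_prob: float = 12.0 / 13.0
    winter_dispersal_doy_mean: float = 362.0   # ~28 Dec
    winter_dispersal_doy_sd: float = 8.0
    winter_return_prob: float = 0.75
    winter_return_doy_mean: float = 72.0       # ~13 Mar
    winter_return_doy_sd: float = 8.0

    prebreeding_prob: float = 9.0 / 13.0
    prebreeding_refuel_days: tuple[float, float] = (4.0, 1.0)  # mean, sd
    prebreeding_km: tuple[float, float] = (204.0, 146.0)
    prebreeding_km_range: tuple[float, float] = (100.0, 540.0)
    prebreeding_away_days: tuple[float, float] = (17.0, 6.0)
    prebreeding_away_range: tuple[float, float] = (7.0, 27.0)

    def __post_init__(self) -> None:
        for probs in (self.n_stopovers_probs_autumn,
                      self.n_stopovers_probs_spring):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise SimConfigError("stopover probabilities must sum to 1")
        if abs(sum(self.lc_probs.values()) - 1.0) > 1e-9:
            raise SimConfigError("lc_probs must sum to 1")
        if self.flight_speed_kmh <= 0:
            raise SimConfigError("flight speed must be positive")
        if any(s <= 0 for s in self.lc_sigma_m.values()):
            raise SimConfigError("error scales must be positive")
        if self.duty_on_hours <= 0 or self.duty_off_hours < 0:
            raise SimConfigError("invalid duty cycle")


@dataclasses.dataclass
class TruthStopover:
    season: str
    centroid: tuple[float, float]
    start: dt.datetime
    end: dt.datetime


@dataclasses.dataclass
class GroundTruth:
    """Truth record consistent with the emitted track timeline."""

    animal_id: str
    fix_times: np.ndarray
    outlier_mask: np.ndarray
    autumn_departure: dt.datetime
    autumn_arrival: dt.datetime
    spring_departure: dt.datetime
    spring_arrival: dt.datetime
    stopovers: list
    winter_events: list            # (from_name, to_name, instant)
    prebreeding: dict | None

    def stopover_count(self, season: str) -> int:
        return sum(1 for s in self.stopovers if s.season == season)


# --------------------------------------------------------------------------
# spherical helpers
# --------------------------------------------------------------------------

def _to_unit(lat: float, lon: float) -> np.ndarray:
    p, l = math.radians(lat), math.radians(lon)
    return np.array([math.cos(p) * math.cos(l),
                     math.cos(p) * math.sin(l), math.sin(p)])


def _from_unit(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lat, lon


def _slerp(p0, p1, f: np.ndarray) -> np.ndarray:
    u0, u1 = _to_unit(*p0), _to_unit(*p1)
    dot = float(np.clip(np.dot(u0, u1), -1.0, 1.0))
    theta = math.acos(dot)
    f = np.asarray(f)[:, None]
    if theta < 1e-9:
        v = (1 - f) * u0 + f * u1
    else:
        v = (np.sin((1 - f) * theta) * u0 + np.sin(f * theta) * u1) / math.sin(theta)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def destination_point(origin: tuple[float, float], bearing_deg: float,
                      distance_km: float) -> tuple[float, float]:
    """Great-circle destination from origin along a bearing."""
    delta = distance_km / EARTH_RADIUS_KM
    theta = math.radians(bearing_deg)
    p1 = math.radians(origin[0])
    lat2 = math.asin(math.sin(p1) * math.cos(delta)
                     + math.cos(p1) * math.sin(delta) * math.cos(theta))
    lon2 = math.radians(origin[1]) + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(p1),
        math.cos(delta) - math.sin(p1) * math.sin(lat2))
    return math.degrees(lat2), (math.degrees(lon2) + 540.0) % 360.0 - 180.0


def _doy_instant(year: int, doy: float) -> dt.datetime:
    """An instant ``doy`` (1-based, fractional) days into ``year``."""
    return (dt.datetime(year, 1, 1, tzinfo=_UTC)
            + dt.timedelta(days=float(doy) - 1.0))


# --------------------------------------------------------------------------
# trajectory construction
# --------------------------------------------------------------------------

@dataclasses.dataclass
class _Phase:
    t0: float
    t1: float
    kind: str                      # "residence" | "flight"
    a: tuple[float, float]
    b: tuple[float, float] | None = None


class _Timeline:
    def __init__(self) -> None:
        self.phases: list[_Phase] = []

    @property
    def t(self) -> float:
        return self.phases[-1].t1

    def start(self, center, t0: float, until: float) -> None:
        self.phases.append(_Phase(t0, until, "residence", center))

    def fly(self, dest, speed_kmh: float) -> float:
        """Append a flight to ``dest``; returns arrival epoch."""
        cur = self.phases[-1]
        origin = cur.b if cur.kind == "flight" else cur.a
        dist = haversine_km(origin, dest)
        dur = dist / speed_kmh * 3600.0
        self.phases.append(_Phase(self.t, self.t + dur, "flight", origin, dest))
        return self.t

    def validate(self) -> None:
        for p, q in zip(self.phases, self.phases[1:]):
            if q.t0 != p.t1 or q.t1 < q.t0:
                raise SimConfigError("phase timeline is not contiguous")


def _flight_region_entry(phase: _Phase, regions: list[Region]) -> float | None:
    """First instant during a flight at which the position lies inside
    any of ``regions`` (2-minute sampling along the great circle)."""
    n = max(2, int((phase.t1 - phase.t0) / 120.0))
    f = np.linspace(0.0, 1.0, n)
    lat, lon = _from_unit(_slerp(phase.a, phase.b, f))
    inside = np.zeros(n, dtype=bool)
    for reg in regions:
        inside |= reg.contains_many(lat, lon)
    hits = np.flatnonzero(inside)
    if hits.size == 0:
        return None
    return float(phase.t0 + f[hits[0]] * (phase.t1 - phase.t0))


def simulate_annual_track(config: SimConfig | None = None,
                          animal_id: str = "SIM",
                          winter_regions: list[Region] | None = None
                          ) -> tuple[Track, GroundTruth]:
    """Simulate one annual cycle; returns the duty-cycled, noisy track
    and its ground truth.  Identical configs (same seed) give bitwise
    identical output."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    if winter_regions is None:
        winter_regions = [r for r in load_regions()
                          if isinstance(r, PolygonRegion)]
    speed = cfg.flight_speed_kmh
    year = cfg.year

    # --- autumn ---------------------------------------------------------
    dep_doy = float(np.clip(rng.normal(cfg.autumn_departure_doy_mean,
                                       cfg.autumn_departure_doy_sd), 195, 250))
    dep_t = (_doy_instant(year, dep_doy)
             + dt.timedelta(hours=float(rng.uniform(0, 24)))).timestamp()
    t_start = dep_t - 15 * 86400.0

    n_stop_a = int(rng.choice(6, p=cfg.n_stopovers_probs_autumn))
    fracs = _spaced_fractions(rng, n_stop_a, lo=0.2, hi=0.85, min_gap=0.08)
    bulge = (rng.uniform(1.2, 2.6) if rng.random() < cfg.inverted_v_prob
             else rng.uniform(0.0, 0.4))
    waypoints = []
    for f in fracs:
        lat = (cfg.colony[0] + f * (cfg.winter_site_a[0] - cfg.colony[0])
               + bulge * math.sin(math.pi * f) + rng.normal(0.0, 0.1))
        lon = (cfg.colony[1] + f * (cfg.winter_site_a[1] - cfg.colony[1])
               + rng.normal(0.0, 0.1))
        waypoints.append((lat, lon))
    dur_a = _stopover_durations(rng, n_stop_a, cfg)

    tl = _Timeline()
    tl.start(cfg.colony, t_start, dep_t)
    truth_stop: list[TruthStopover] = []
    for wp, d in zip(waypoints, dur_a):
        t_arr = tl.fly(wp, speed)
        t_leave = tl.t + d * 86400.0
        tl.phases.append(_Phase(tl.t, t_leave, "residence", wp))
        truth_stop.append(TruthStopover("autumn", wp,
                                        epoch_to_datetime(t_arr),
                                        epoch_to_datetime(t_leave)))
    tl.fly(cfg.winter_site_a, speed)
    entry = _flight_region_entry(tl.phases[-1], winter_regions)
    autumn_arrival = epoch_to_datetime(entry if entry is not None else tl.t)

    # --- wintering ------------------------------------------------------
    winter_events = []
    at_b = False
    if rng.random() < cfg.winter_dispersal_prob:
        disp_doy = rng.normal(cfg.winter_dispersal_doy_mean,
                              cfg.winter_dispersal_doy_sd)
        disp_t = max(_doy_instant(year, float(disp_doy)).timestamp(),
                     tl.t + 5 * 86400.0)
        tl.phases.append(_Phase(tl.t, disp_t, "residence", cfg.winter_site_a))
        tl.fly(cfg.winter_site_b, speed)
        winter_events.append(("Bohai Bay", "Laizhou Bay",
                              epoch_to_datetime(
                                  0.5 * (tl.phases[-1].t0 + tl.phases[-1].t1))))
        at_b = True
        if rng.random() < cfg.winter_return_prob:
            ret_doy = rng.normal(cfg.winter_return_doy_mean,
                                 cfg.winter_return_doy_sd)
            ret_t = max(_doy_instant(year + 1, float(ret_doy)).timestamp(),
                        tl.t + 10 * 86400.0)
            tl.phases.append(_Phase(tl.t, ret_t, "residence", cfg.winter_site_b))
            tl.fly(cfg.winter_site_a, speed)
            winter_events.append(("Laizhou Bay", "Bohai Bay",
                                  epoch_to_datetime(
                                      0.5 * (tl.phases[-1].t0 + tl.phases[-1].t1))))
            at_b = False

    # --- spring ---------------------------------------------------------
    spr_doy = float(np.clip(rng.normal(cfg.spring_departure_doy_mean,
                                       cfg.spring_departure_doy_sd), 80, 120))
    spr_t = max((_doy_instant(year + 1, spr_doy)
                 + dt.timedelta(hours=float(rng.uniform(0, 24)))).timestamp(),
                tl.t + 5 * 86400.0)
    here = cfg.winter_site_b if at_b else cfg.winter_site_a
    tl.phases.append(_Phase(tl.t, spr_t, "residence", here))
    spring_departure = epoch_to_datetime(spr_t)

    n_stop_s = int(rng.choice(6, p=cfg.n_stopovers_probs_spring))
    for f in _spaced_fractions(rng, n_stop_s, lo=0.3, hi=0.7, min_gap=0.1):
        lat = (here[0] + f * (cfg.colony[0] - here[0])
               + rng.uniform(-0.8, 0.2))
        lon = here[1] + f * (cfg.colony[1] - here[1]) + rng.normal(0.0, 0.1)
        t_arr = tl.fly((lat, lon), speed)
        d = min(cfg.stopover_duration_min_days
                + rng.gamma(1.0, 2.0), 6.0)
        t_leave = tl.t + d * 86400.0
        tl.phases.append(_Phase(tl.t, t_leave, "residence", (lat, lon)))
        truth_stop.append(TruthStopover("spring", (lat, lon),
                                        epoch_to_datetime(t_arr),
                                        epoch_to_datetime(t_leave)))
    tl.fly(cfg.colony, speed)
    colony_disc = DiscRegion("colony", cfg.colony, 20.0)
    entry = _flight_region_entry(tl.phases[-1], [colony_disc])
    spring_arrival = epoch_to_datetime(entry if entry is not None else tl.t)

    # --- pre-breeding dispersal -----------------------------------------
    prebreeding = None
    if rng.random() < cfg.prebreeding_prob:
        refuel = float(np.clip(rng.normal(*cfg.prebreeding_refuel_days), 2, 7))
        leave_t = tl.t + refuel * 86400.0
        tl.phases.append(_Phase(tl.t, leave_t, "residence", cfg.colony))
        km = float(np.clip(rng.normal(*cfg.prebreeding_km),
                           *cfg.prebreeding_km_range))
        bearing = float(rng.uniform(-90.0, 45.0)) % 360.0   # W through N to NE
        dest = destination_point(cfg.colony, bearing, km)
        away = float(np.clip(rng.normal(*cfg.prebreeding_away_days),
                             *cfg.prebreeding_away_range))
        tl.fly(dest, speed)
        flight_h = (tl.phases[-1].t1 - tl.phases[-1].t0) / 3600.0
        stay = max(away * 24.0 - 2.0 * flight_h, 48.0)
        tl.phases.append(_Phase(tl.t, tl.t + stay * 3600.0, "residence", dest))
        tl.fly(cfg.colony, speed)
        prebreeding = {"start": epoch_to_datetime(leave_t),
                       "excursion_km": km,
                       "duration_days": (2.0 * flight_h + stay) / 24.0}
    tl.phases.append(_Phase(tl.t, tl.t + 10 * 86400.0, "residence", cfg.colony))
    tl.validate()

    # --- duty-cycled sampling ------------------------------------------
    t_end = tl.t
    cycle = (cfg.duty_on_hours + cfg.duty_off_hours) * 3600.0
    offset = float(rng.uniform(0.0, cycle))
    times = np.arange(t_start, t_end, cfg.sample_interval_hours * 3600.0)
    on = ((times - t_start + offset) % cycle) < cfg.duty_on_hours * 3600.0
    times = times[on]

    lat, lon = _positions(tl, times, cfg, rng)

    # --- location classes, error and outliers ---------------------------
    classes = np.array(list(cfg.lc_probs.keys()), dtype=object)
    probs = np.array(list(cfg.lc_probs.values()))
    lc = rng.choice(classes, size=len(times), p=probs)
    outlier = rng.random(len(times)) < cfg.outlier_rate
    aux = np.array(["0", "A", "B"], dtype=object)
    aux_p = np.array([cfg.lc_probs[c] for c in aux])
    aux_p = aux_p / aux_p.sum()
    lc[outlier] = rng.choice(aux, size=int(outlier.sum()), p=aux_p)

    sigma_km = np.array([cfg.lc_sigma_m[c] for c in lc]) / 1000.0
    # per-axis sd sigma/sqrt(2) so the RMS planar displacement is sigma
    dx = rng.normal(0.0, 1.0, len(times)) * sigma_km / math.sqrt(2.0)
    dy = rng.normal(0.0, 1.0, len(times)) * sigma_km / math.sqrt(2.0)
    km_per_deg = math.pi * EARTH_RADIUS_KM / 180.0
    lat = lat + dy / km_per_deg
    lon = lon + dx / (km_per_deg * np.cos(np.radians(lat)))

    n_out = int(outlier.sum())
    if n_out:
        d_out = rng.uniform(*cfg.outlier_km_range, size=n_out)
        b_out = rng.uniform(0.0, 360.0, size=n_out)
        for k, i in enumerate(np.flatnonzero(outlier)):
            lat[i], lon[i] = destination_point((lat[i], lon[i]),
                                               float(b_out[k]), float(d_out[k]))

    track = Track(animal_id, times, lat, lon, lc)
    truth = GroundTruth(
        animal_id=animal_id, fix_times=times, outlier_mask=outlier,
        autumn_departure=epoch_to_datetime(dep_t),
        autumn_arrival=autumn_arrival,
        spring_departure=spring_departure,
        spring_arrival=spring_arrival,
        stopovers=truth_stop, winter_events=winter_events,
        prebreeding=prebreeding)
    return track, truth


def _spaced_fractions(rng, n: int, lo: float, hi: float,
                      min_gap: float) -> np.ndarray:
    """Sorted route fractions with a minimum spacing (stopover sites
    must be separable at the 20-km clustering radius)."""
    if n == 0:
        return np.empty(0)
    for _ in range(200):
        f = np.sort(rng.uniform(lo, hi, size=n))
        if n == 1 or np.min(np.diff(f)) >= min_gap:
            return f
    return np.linspace(lo, hi, n)


def _stopover_durations(rng, n: int, cfg: SimConfig) -> np.ndarray:
    shape, scale = cfg.stopover_duration_gamma
    d = cfg.stopover_duration_min_days + rng.gamma(shape, scale, size=n)
    return np.minimum(d, cfg.stopover_duration_max_days)


def _ou_walk(rng, times: np.ndarray, sd: float, tau_hours: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck excursion sampled at the given
    instants: mean-reverting within-site movement with stationary
    standard deviation ``sd`` and relaxation time ``tau_hours``."""
    n = len(times)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    if n > 1:
        dt_h = np.diff(times) / 3600.0
        phi = np.exp(-dt_h / tau_hours)
        innov = rng.normal(0.0, 1.0, n - 1) * sd * np.sqrt(1.0 - phi ** 2)
        for k in range(1, n):
            x[k] = x[k - 1] * phi[k - 1] + innov[k - 1]
    return x


def _positions(tl: _Timeline, times: np.ndarray, cfg: SimConfig,
               rng) -> tuple[np.ndarray, np.ndarray]:
    starts = np.array([p.t0 for p in tl.phases])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1,
                  0, len(tl.phases) - 1)
    lat = np.empty(len(times))
    lon = np.empty(len(times))
    sd_deg_lat = (cfg.residence_radius_km / 2.0) / (math.pi * EARTH_RADIUS_KM / 180.0)
    for k, ph in enumerate(tl.phases):
        m = idx == k
        nm = int(m.sum())
        if nm == 0:
            continue
        if ph.kind == "residence":
            clat, clon = ph.a
            jlat = _ou_walk(rng, times[m], sd_deg_lat, cfg.residence_tau_hours)
            jlon = _ou_walk(rng, times[m],
                            sd_deg_lat / math.cos(math.radians(clat)),
                            cfg.residence_tau_hours)
            lat[m] = clat + jlat
            lon[m] = clon + jlon
        else:
            f = (times[m] - ph.t0) / max(ph.t1 - ph.t0, 1e-9)
            la, lo_ = _from_unit(_slerp(ph.a, ph.b, np.clip(f, 0.0, 1.0)))
            lat[m] = la
            lon[m] = lo_
    return lat, lon


# --------------------------------------------------------------------------
# recovery evaluation
# --------------------------------------------------------------------------

@dataclasses.dataclass
class TrackEstimate:
    """Pipeline output for one simulated track, ready for scoring."""

    animal_id: str
    journeys: list
    stopovers: list
    removed: list                  # (ArgosFix, reason) from the filter


@dataclasses.dataclass
class RecoveryReport:
    """Aggregate recovery metrics over a batch of simulated tracks."""

    n_tracks: int
    departure_mae_days: float
    arrival_mae_days: float
    stopover_count_accuracy: float
    stopover_precision: float
    stopover_recall: float
    outlier_recall: float
    false_removal_rate: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def evaluate_recovery(estimates: list[TrackEstimate],
                      truths: list[GroundTruth],
                      match_radius_km: float = 20.0) -> RecoveryReport:
    """Score estimated journeys/stopovers and filter decisions against
    ground truth.

    A stopover matches a truth stopover when the centroids are within
    ``match_radius_km`` and the intervals overlap.  Outlier recall is
    the fraction of injected outliers the filter removed (any reason);
    the false-removal rate is the fraction of genuine fixes removed.
    """
    if [e.animal_id for e in estimates] != [t.animal_id for t in truths]:
        raise ValueError("estimate/truth animal ids do not match")
    dep_err, arr_err = [], []
    n_count_ok = n_aut = 0
    tp = fp = fn = 0
    n_out_removed = n_out = n_true_removed = n_true = 0

    for est, tru in zip(estimates, truths):
        aut = [j for j in est.journeys if j.season == "autumn"]
        true_aut = [s for s in tru.stopovers if s.season == "autumn"]
        n_aut += 1
        if aut:
            j = aut[0]
            if j.departure.date is not None:
                dep_err.append(abs(nonleap_days_between(
                    tru.autumn_departure.date(), j.departure.date)))
            if j.arrival.date is not None:
                arr_err.append(abs(nonleap_days_between(
                    tru.autumn_arrival.date(), j.arrival.date)))
            if j.n_stopovers == len(true_aut):
                n_count_ok += 1
            matched = set()
            for s in j.stopovers:
                hit = None
                for q, ts in enumerate(true_aut):
                    if q in matched:
                        continue
                    if (haversine_km(s.centroid, ts.centroid) <= match_radius_km
                            and s.start <= ts.end and ts.start <= s.end):
                        hit = q
                        break
                if hit is None:
                    fp += 1
                else:
                    matched.add(hit)
                    tp += 1
            fn += len(true_aut) - len(matched)

        removed_times = {f.timestamp.timestamp() for f, _ in est.removed}
        out_times = set(tru.fix_times[tru.outlier_mask].tolist())
        true_times = set(tru.fix_times[~tru.outlier_mask].tolist())
        n_out += len(out_times)
        n_true += len(true_times)
        n_out_removed += len(out_times & removed_times)
        n_true_removed += len(true_times & removed_times)

    return RecoveryReport(
        n_tracks=len(estimates),
        departure_mae_days=float(np.mean(dep_err)) if dep_err else math.nan,
        arrival_mae_days=float(np.mean(arr_err)) if arr_err else math.nan,
        stopover_count_accuracy=n_count_ok / n_aut if n_aut else math.nan,
        stopover_precision=tp / (tp + fp) if tp + fp else 1.0,
        stopover_recall=tp / (tp + fn) if tp + fn else 1.0,
        outlier_recall=n_out_removed / n_out if n_out else math.nan,
        false_removal_rate=n_true_removed / n_true if n_true else math.nan,
    )


def run_recovery_study(n_tracks: int = 100, base_seed: int = 0,
                       config: SimConfig | None = None) -> RecoveryReport:
    """Simulate ``n_tracks`` annual cycles, run the filter and the
    segmentation stage on each, and score recovery against truth."""
    base_cfg = config or SimConfig()
    regions = load_regions()
    winter = [r for r in regions if isinstance(r, PolygonRegion)]
    breeding = next(r for r in regions if isinstance(r, DiscRegion))
    fc = argos_filter.FilterConfig()

    estimates, truths = [], []
    for i in range(n_tracks):
        cfg = dataclasses.replace(base_cfg, seed=(base_seed + i) % (2 ** 31))
        track, truth = simulate_annual_track(cfg, animal_id=f"S{i:03d}",
                                             winter_regions=winter)
        res = argos_filter.filter_track(track, fc)
        stops = segmentation.detect_stopovers(res.kept)
        journeys = segmentation.delineate_journeys(
            res.kept, breeding, winter, stopovers=stops)
        estimates.append(TrackEstimate(track.animal_id, journeys, stops,
                                       res.removed))
        truths.append(truth)
    return evaluate_recovery(estimates, truths)
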