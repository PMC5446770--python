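"""Plausibility filtering of Argos Doppler fixes.

Removes implausible auxiliary locations using the distance-moved,
movement-rate and turning-angle logic of classic Argos track filters.
Standard-class fixes (LC at or above a configurable threshold, default
LC 1) are always retained; LC Z fixes are always removed.  An auxiliary
fix survives if it is near-duplicate consistent with a temporal
neighbour, and is removed if it implies an unsustainable movement rate
to both surviving neighbours or forms a sharp out-and-back spike.
Removal is re-evaluated iteratively until a fixpoint.

This is a re-implementation of the published distance/rate/angle
contract, not a port of any particular filter release; all thresholds
are configuration-exposed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .track_io import LC_RANK, Track, _haversine_arr

REASON_RATE = "rate"
REASON_SPIKE = "spike"
REASON_CLASS_Z = "class_Z"


class TrackTooShortError(ValueError):
    """Filtering needs at least three fixes."""


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the plausibility filter.

    keep_lc_at_or_above
        Location class at or above which fixes are exempt from
        filtering (default "1": LC 1-3 always kept).
    max_sustained_rate_kmh
        Movement rate above which an implied speed is implausible.
        Observed sustained flight in this system is ~30-45 km/h, so the
        90 km/h default never flags true flight.
    redundant_dist_km
        A fix within this distance of a temporal neighbour is
        considered a near-duplicate and kept.
    spike_angle_deg
        Internal angle below which an out-and-back excursion is a spike.
    spike_dist_km
        Leg length both legs of a spike must exceed.  This scale is
        deliberately separate from (and much larger than) the
        redundancy scale: class-typical positional wobble of auxiliary
        fixes reaches tens of km and must never be mistaken for a
        spike, whereas genuine gross outliers sit >= 100 km off path.
    max_iterations
        Upper bound on re-evaluation passes.
    """

    keep_lc_at_or_above: str = "1"
    max_sustained_rate_kmh: float = 90.0
    redundant_dist_km: float = 3.0
    spike_angle_deg: float = 15.0
    spike_dist_km: float = 50.0
    max_iterations: int = 20

    def __post_init__(self) -> None:
        if self.keep_lc_at_or_above not in LC_RANK:
            raise ValueError(f"unknown LC {self.keep_lc_at_or_above!r}")
        if self.max_sustained_rate_kmh <= 0 or self.redundant_dist_km <= 0:
            raise ValueError("rates and distances must be positive")
        if not 0.0 < self.spike_angle_deg < 180.0:
            raise ValueError("spike_angle_deg must be in (0, 180)")
        if self.spike_dist_km <= 0:
            raise ValueError("spike_dist_km must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclasses.dataclass
class FilterResult:
    """Outcome of :func:`filter_track`.

    ``kept`` and ``removed`` partition the input fixes; ``removed``
    pairs each rejected fix with its reason (rate, spike or class_Z).
    """

    kept: Track
    removed: list  # list[(ArgosFix, reason)]
    n_iterations: int
    empty_after_filtering: bool = False


def _internal_angle_deg(leg_prev: np.ndarray, leg_next: np.ndarray,
                        base: np.ndarray) -> np.ndarray:
    """Planar internal angle at the middle vertex from triangle side
    lengths (law of cosines).  Adequate at sub-Earth-radius scales."""
    with np.errstate(invalid="ignore", divide="ignore"):
        cosv = (leg_prev ** 2 + leg_next ** 2 - base ** 2) / (
            2.0 * leg_prev * leg_next)
    return np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))


def filter_track(track: Track, config: FilterConfig | None = None) -> FilterResult:
    """Remove implausible auxiliary Doppler fixes from a track.

    Iterates to a fixpoint (or ``max_iterations``): each pass evaluates
    every currently kept auxiliary fix against its surviving temporal
    neighbours.  When two adjacent fixes mutually imply an excess rate,
    the one with the worse location class is removed (the later one on
    ties), and the survivor is re-evaluated on the next pass.
    """
    if config is None:
        config = FilterConfig()
    n = len(track)
    if n < 3:
        raise TrackTooShortError(f"need >= 3 fixes, got {n}")

    rank = track.lc_rank()
    protected = rank >= LC_RANK[config.keep_lc_at_or_above]
    status = np.zeros(n, dtype=int)  # 0 kept, 1 rate, 2 spike, 3 class_Z
    is_z = np.array([c == "Z" for c in track.lc])
    status[is_z] = 3

    vmax = config.max_sustained_rate_kmh
    dmin = config.redundant_dist_km
    amax = config.spike_angle_deg

    n_iter = 0
    for n_iter in range(1, config.max_iterations + 1):
        kept_idx = np.flatnonzero(status == 0)
        m = len(kept_idx)
        if m < 3:
            break
        lat = track.lat[kept_idx]
        lon = track.lon[kept_idx]
        t = track.t[kept_idx]

        d_prev = np.full(m, np.inf)
        d_next = np.full(m, np.inf)
        d_prev[1:] = _haversine_arr(lat[1:], lon[1:], lat[:-1], lon[:-1])
        d_next[:-1] = d_prev[1:]
        dt_prev = np.full(m, np.inf)
        dt_next = np.full(m, np.inf)
        dt_prev[1:] = (t[1:] - t[:-1]) / 3600.0
        dt_next[:-1] = dt_prev[1:]

        with np.errstate(divide="ignore", invalid="ignore"):
            v_prev = np.where(dt_prev > 0, d_prev / dt_prev,
                              np.where(d_prev > dmin, np.inf, 0.0))
            v_next = np.where(dt_next > 0, d_next / dt_next,
                              np.where(d_next > dmin, np.inf, 0.0))
        # ends have a single neighbour; treat the missing side as passing
        v_prev[0] = 0.0
        v_next[-1] = 0.0

        base = np.full(m, np.nan)
        if m >= 3:
            base[1:-1] = _haversine_arr(lat[:-2], lon[:-2], lat[2:], lon[2:])
        angle = _internal_angle_deg(d_prev, d_next, base)

        aux = ~protected[kept_idx]
        redundant = (d_prev <= dmin) | (d_next <= dmin)
        rate_flag = aux & ~redundant & (v_prev > vmax) & (v_next > vmax)
        spike_flag = (aux & ~redundant & ~rate_flag
                      & (d_prev > config.spike_dist_km)
                      & (d_next > config.spike_dist_km)
                      & np.isfinite(base) & (angle < amax))

        cand = np.flatnonzero(rate_flag | spike_flag)
        if cand.size == 0:
            break

        # mutual-excess tie-break: of two adjacent rate candidates keep
        # the better class (earlier fix on ties)
        drop = set(cand.tolist())
        for j in cand:
            if rate_flag[j] and j + 1 in drop and rate_flag[j + 1]:
                ri, rj = rank[kept_idx[j]], rank[kept_idx[j + 1]]
                spare = j if ri > rj else (j + 1 if rj > ri else j)
                drop.discard(spare)
        if not drop:
            drop = set(cand.tolist()[:1])
        for j in drop:
            status[kept_idx[j]] = 1 if rate_flag[j] else 2
    else:
        n_iter = config.max_iterations

    kept_mask = status == 0
    kept = track.subset(kept_mask)
    reason_name = {1: REASON_RATE, 2: REASON_SPIKE, 3: REASON_CLASS_Z}
    removed = [(track.fix(i), reason_name[status[i]])
               for i in np.flatnonzero(~kept_mask)]
    empty = kept.n == 0 if len(kept.t) == 0 else False
    result = FilterResult(kept=kept, removed=removed, n_iterations=n_iter,
                          empty_after_filtering=bool(empty))
    if result.empty_after_filtering:
        warnings.warn(f"track {track.animal_id}: no fixes survived filtering")
    return result
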