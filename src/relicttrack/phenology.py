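"""Between/within-individual migration statistics.

One-way ANOVA with individual as the factor quantifies
between-individual variation in migration timing and route; the
intraclass correlation (repeatability) of Lessells & Boag follows from
the ANOVA mean squares with the effective group size

    n0 = (N − Σ nᵢ²/N) / (a − 1),
    s²_A = (MS_between − MS_within) / n0,
    r = s²_A / (s²_A + MS_within).

Two-sample comparisons use the pooled-variance Student t-test (the
convention that reproduces the reference results; Welch is not used),
and individual autumn-vs-spring distances use a paired t-test on
per-individual means.  Date variables enter as non-leap day-of-year
integers; all journeys of one season fall within a three-month window,
so linear (non-circular) means are safe.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dispersal import residence_duration
from .track_io import JourneyRecord, date_from_nonleap_doy


class DegenerateDataError(ValueError):
    """Zero within-group (or within-pair) variance."""


@dataclasses.dataclass
class GroupedObservations:
    """Repeated measurements grouped by individual."""

    groups: dict

    def __post_init__(self) -> None:
        self.groups = {k: [float(v) for v in vals]
                       for k, vals in self.groups.items()}
        if self.a < 2:
            raise ValueError("need >= 2 groups")
        if any(len(v) == 0 for v in self.groups.values()):
            raise ValueError("every group must be non-empty")
        if self.N <= self.a:
            raise ValueError("need more observations than groups")

    @property
    def a(self) -> int:
        return len(self.groups)

    @property
    def N(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def values(self) -> list[list[float]]:
        return [self.groups[k] for k in self.groups]


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    F: float
    p: float


@dataclasses.dataclass(frozen=True)
class RepeatabilityResult:
    n0: float
    s2_among: float
    r: float
    anova: AnovaResult


@dataclasses.dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    kind: str


def oneway_anova(obs: GroupedObservations) -> AnovaResult:
    """Standard one-way decomposition; F = MS_between / MS_within with
    the p-value from the F(a−1, N−a) distribution."""
    groups = [np.asarray(g, dtype=float) for g in obs.values()]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df_b, df_w = obs.a - 1, obs.N - obs.a
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0.0:
        raise DegenerateDataError("zero within-group variance")
    F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(df_between=df_b, df_within=df_w,
                       ms_between=float(ms_b), ms_within=float(ms_w),
                       F=float(F), p=p)


def repeatability(obs: GroupedObservations) -> RepeatabilityResult:
    """Intraclass correlation from one-way ANOVA mean squares
    (Lessells & Boag).  ``r`` may be negative when MS_between falls
    below MS_within; it is returned unclamped."""
    if not any(len(g) >= 2 for g in obs.values()):
        raise ValueError("need at least one group with >= 2 observations")
    res = oneway_anova(obs)
    ns = np.array([len(g) for g in obs.values()], dtype=float)
    N = float(ns.sum())
    n0 = (N - float((ns ** 2).sum()) / N) / (obs.a - 1)
    s2_among = (res.ms_between - res.ms_within) / n0
    r = s2_among / (s2_among + res.ms_within)
    return RepeatabilityResult(n0=float(n0), s2_among=float(s2_among),
                               r=float(r), anova=res)


def pooled_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sample Student t-test with pooled variance (df n1+n2−2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per sample")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        raise DegenerateDataError("zero pooled variance")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(t), df=len(x) + len(y) - 2, p=float(p),
                       kind="pooled")


def paired_t_test(x: Sequence[float], y: Sequence[float] | None = None) -> TTestResult:
    """Paired t-test on within-pair differences (df n−1).

    Call with two equal-length sequences, or a single sequence of
    (x, y) pairs.
    """
    if y is None:
        pairs = list(x)
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 pairs of equal length")
    d = x - y
    if np.var(d, ddof=1) == 0.0:
        if d.mean() == 0.0:
            return TTestResult(t=0.0, df=len(d) - 1, p=1.0, kind="paired")
        raise DegenerateDataError("zero-variance nonzero-mean differences")
    t, p = sps.ttest_rel(x, y)
    return TTestResult(t=float(t), df=len(x) - 1, p=float(p), kind="paired")


# --------------------------------------------------------------------------
# journey-table helpers
# --------------------------------------------------------------------------

_VARIABLES = {
    "departure_doy": lambda j: j.departure_doy,
    "arrival_doy": lambda j: j.arrival_doy,
    "duration_days": lambda j: j.duration_days,
    "total_km": lambda j: j.total_km,
    "n_stopovers": lambda j: j.n_stopovers,
}


def journey_groups(journeys: Iterable[JourneyRecord], variable: str,
                   season: str, individuals: Sequence[str] | None = None,
                   min_journeys: int = 1) -> GroupedObservations:
    """Group one journey variable by individual for ANOVA/repeatability.

    ``individuals`` restricts to the named birds (e.g. those with at
    least two round trips); ``min_journeys`` drops smaller groups.
    """
    getter = _VARIABLES[variable]
    groups: dict[str, list[float]] = {}
    for j in journeys:
        if j.season != season:
            continue
        if individuals is not None and j.individual not in individuals:
            continue
        groups.setdefault(j.individual, []).append(float(getter(j)))
    groups = {k: v for k, v in groups.items() if len(v) >= min_journeys}
    return GroupedObservations(groups=groups)


def round_trip_counts(journeys: Iterable[JourneyRecord]) -> dict[str, int]:
    """Complete round trips per individual (paired autumn+spring
    seasons, i.e. the smaller of the two season counts)."""
    autumn: dict[str, int] = {}
    spring: dict[str, int] = {}
    for j in journeys:
        d = autumn if j.season == "autumn" else spring
        d[j.individual] = d.get(j.individual, 0) + 1
    return {i: min(autumn.get(i, 0), spring.get(i, 0))
            for i in set(autumn) | set(spring)}


def segment_classes(journeys: Iterable[JourneyRecord],
                    season: str = "autumn") -> tuple[list[float], list[float]]:
    """Split segments of multi-stopover journeys (>= 2 stopovers) into
    first/last versus middle segments."""
    first_last: list[float] = []
    middle: list[float] = []
    for j in journeys:
        if j.season != season or j.n_stopovers < 2:
            continue
        segs = list(j.segment_lengths_km)
        first_last += [segs[0], segs[-1]]
        middle += segs[1:-1]
    return first_last, middle


def wintering_residences(journeys: Iterable[JourneyRecord]) -> list[int]:
    """Wintering residence durations: each autumn arrival paired with
    the same individual's next-spring departure (non-leap convention)."""
    journeys = list(journeys)
    out = []
    for j in journeys:
        if j.season != "autumn":
            continue
        nxt = [k for k in journeys
               if k.season == "spring" and k.individual == j.individual
               and k.year == j.arrival.year + 1]
        if nxt:
            out.append(residence_duration(j.arrival, nxt[0].departure))
    return out


def paired_season_distances(journeys: Iterable[JourneyRecord]) -> tuple[list, list, list]:
    """Per-individual mean autumn and spring total distances for the
    individuals tracked in both seasons (inputs to the paired t-test)."""
    journeys = list(journeys)
    inds = sorted({j.individual for j in journeys if j.season == "spring"}
                  & {j.individual for j in journeys if j.season == "autumn"},
                  key=lambda s: (len(s), s))
    aut = [float(np.mean([j.total_km for j in journeys
                          if j.individual == i and j.season == "autumn"]))
           for i in inds]
    spr = [float(np.mean([j.total_km for j in journeys
                          if j.individual == i and j.season == "spring"]))
           for i in inds]
    return inds, aut, spr


def summarize_journeys(journeys: Iterable[JourneyRecord]) -> pd.DataFrame:
    """Per-season summary: mean, SD and range of departure/arrival
    day-of-year (displayed as calendar dates), duration, stopover count
    and total distance.  SD is NaN for single-journey cells."""
    journeys = list(journeys)
    rows = []
    for season in ("autumn", "spring"):
        js = [j for j in journeys if j.season == season]
        if not js:
            continue
        for var in ("departure_doy", "arrival_doy", "duration_days",
                    "n_stopovers", "total_km"):
            vals = np.array([float(_VARIABLES[var](j)) for j in js])
            mean = float(vals.mean())
            row = {
                "season": season, "variable": var, "n": len(vals),
                "mean": mean,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "min": float(vals.min()), "max": float(vals.max()),
            }
            if var.endswith("_doy"):
                row["mean_date"] = date_from_nonleap_doy(mean).strftime("%d %b")
                row["min_date"] = date_from_nonleap_doy(row["min"]).strftime("%d %b")
                row["max_date"] = date_from_nonleap_doy(row["max"]).strftime("%d %b")
            rows.append(row)
    return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """Display formatting: three decimals, '<0.001' below that."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"
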