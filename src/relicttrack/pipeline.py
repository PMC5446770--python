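"""End-to-end orchestration: filter -> segment -> dispersal ->
home range -> statistics, plus a stats-only entry point that consumes a
journey table directly (so the packaged reference journeys can drive
the statistics layer without raw fixes).

All artifacts are delimited text or GeoJSON and are byte-identical
across runs with identical inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .argos_filter import FilterConfig, filter_track
from .dispersal import (DiscRegion, PolygonRegion, detect_prebreeding_dispersal,
                        detect_winter_dispersal, load_regions)
from .homerange import isopleth_area, isopleth_geojson, kernel_ud, lscv_bandwidth, project_local
from .phenology import (format_p, journey_groups, oneway_anova,
                        paired_season_distances, paired_t_test, pooled_t_test,
                        repeatability, round_trip_counts, segment_classes,
                        summarize_journeys, wintering_residences)
from .segmentation import delineate_journeys, detect_stopovers
from .track_io import (JourneyRecord, load_table1_fixture, read_fixes,
                       tracks_to_geojson, write_fixes, write_geojson)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclasses.dataclass
class PipelineConfig:
    """Paths and per-stage parameter blocks for one pipeline run."""

    fixes: str | None = None
    regions: str | None = None          # None -> packaged synthetic regions
    outdir: str = "out"
    delimiter: str = ","
    filter: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    stopover_radius_km: float = 20.0
    stopover_min_hours: float = 24.0
    homerange_levels: tuple = (0.5, 0.9)
    run_homerange: bool = True
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        fblock = raw.pop("filter", {})
        cfg = cls(**raw)
        cfg.filter = FilterConfig(**fblock)
        return cfg


def _fmt_date(d: dt.date | None) -> str:
    return d.isoformat() if d is not None else ""


def journeys_frame(journeys) -> pd.DataFrame:
    """Journey list (segmentation output or JourneyRecords) as a table
    mirroring the reference layout."""
    rows = []
    for j in journeys:
        dep = getattr(j.departure, "date", j.departure)
        arr = getattr(j.arrival, "date", j.arrival)
        rows.append({
            "individual": j.individual, "season": j.season, "year": j.year,
            "departure": _fmt_date(dep), "arrival": _fmt_date(arr),
            "n_stopovers": j.n_stopovers,
            "segments_km": "/".join(f"{s:g}" for s in j.segment_lengths_km),
            "total_km": j.total_km,
            "duration_days": j.duration_days,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a fix table; returns the artifact paths and
    headline results.  Any stage failure raises :class:`PipelineError`
    tagged with the stage name."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"outdir": str(out)}
    params = {k: v for k, v in dataclasses.asdict(config).items()
              if k != "outdir"}   # analysis parameters only
    provenance = [f"relicttrack {__version__}", f"config: {params}"]

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return deco

    tracks = stage("read")(lambda: read_fixes(
        config.fixes, delimiter=config.delimiter))
    regions = stage("read")(lambda: load_regions(config.regions))
    breeding = next((r for r in regions if isinstance(r, DiscRegion)), None)
    wintering = [r for r in regions if isinstance(r, PolygonRegion)]

    # --- filter ---------------------------------------------------------
    def _filter():
        kept, removed_rows, results = [], [], {}
        for tr in tracks:
            res = filter_track(tr, config.filter)
            results[tr.animal_id] = res
            kept.append(res.kept)
            for fix, reason in res.removed:
                removed_rows.append((fix.animal_id, fix.timestamp.isoformat(),
                                     fix.lat, fix.lon, fix.lc, reason))
        write_fixes(kept, out / "kept.csv", delimiter=config.delimiter)
        pd.DataFrame(removed_rows, columns=[
            "animal_id", "timestamp", "lat", "lon", "lc", "reason"
        ]).to_csv(out / "removed.csv", index=False, sep=config.delimiter)
        return kept
    kept_tracks = stage("filter")(_filter)
    artifacts["kept"] = str(out / "kept.csv")
    artifacts["removed"] = str(out / "removed.csv")

    # --- segmentation ---------------------------------------------------
    def _segment():
        all_j, stop_feats = [], []
        for tr in kept_tracks:
            stops = detect_stopovers(tr, radius_km=config.stopover_radius_km,
                                     min_hours=config.stopover_min_hours)
            if breeding is not None:
                all_j += delineate_journeys(tr, breeding, wintering,
                                            radius_km=config.stopover_radius_km,
                                            stopovers=stops)
            for s in stops:
                stop_feats.append({
                    "type": "Feature",
                    "properties": {"animal_id": tr.animal_id,
                                   "start": s.start.isoformat(),
                                   "end": s.end.isoformat(),
                                   "duration_days": round(s.duration_days, 3),
                                   "n_fixes": s.n_fixes},
                    "geometry": {"type": "Point",
                                 "coordinates": [round(s.centroid[1], 5),
                                                 round(s.centroid[0], 5)]},
                })
        write_geojson({"type": "FeatureCollection", "features": stop_feats},
                      out / "stopovers.geojson")
        journeys_frame(all_j).to_csv(out / "journeys.csv", index=False,
                                     sep=config.delimiter)
        return all_j
    journeys = stage("segment")(_segment)
    artifacts["journeys"] = str(out / "journeys.csv")
    artifacts["stopovers"] = str(out / "stopovers.geojson")

    # --- dispersal ------------------------------------------------------
    def _dispersal():
        rows = []
        for tr in kept_tracks:
            for ev in detect_winter_dispersal(tr, wintering):
                rows.append((tr.animal_id, ev.kind, ev.from_region,
                             ev.to_region, _fmt_date(ev.date.date), "", ""))
            if breeding is not None:
                aut = [j for j in journeys
                       if j.individual == tr.animal_id and j.season == "spring"
                       and j.arrival.date is not None]
                after = (dt.datetime.combine(aut[0].arrival.date, dt.time(),
                                             tzinfo=dt.timezone.utc)
                         if aut else None)
                if after is not None:
                    for ev in detect_prebreeding_dispersal(
                            tr, breeding.center, after=after):
                        rows.append((tr.animal_id, ev.kind, ev.from_region,
                                     ev.to_region, _fmt_date(ev.date.date),
                                     f"{ev.excursion_km:.1f}",
                                     f"{ev.duration_days:.2f}"))
        pd.DataFrame(rows, columns=["animal_id", "kind", "from", "to", "date",
                                    "excursion_km", "duration_days"]
                     ).to_csv(out / "dispersal.csv", index=False,
                              sep=config.delimiter)
        return rows
    stage("dispersal")(_dispersal)
    artifacts["dispersal"] = str(out / "dispersal.csv")

    # --- home range (pooled wintering locations) ------------------------
    if config.run_homerange:
        def _homerange():
            lats, lons = [], []
            for tr in kept_tracks:
                mask = np.zeros(len(tr), dtype=bool)
                for reg in wintering:
                    mask |= reg.contains_many(tr.lat, tr.lon)
                lats.append(tr.lat[mask])
                lons.append(tr.lon[mask])
            lats = np.concatenate(lats) if lats else np.empty(0)
            lons = np.concatenate(lons) if lons else np.empty(0)
            if len(lats) < 5:
                logger.warning("homerange: <5 pooled wintering fixes; skipped")
                return None
            pts = project_local(lats, lons)
            bw = lscv_bandwidth(pts)
            ud = kernel_ud(pts, bw)
            np.savetxt(out / "ud_grid.txt", ud.density, fmt="%.6e",
                       header=f"x0={ud.x0} y0={ud.y0} cell_km={ud.cell_km} "
                              f"center={ud.center}")
            rows = [(lv, isopleth_area(ud, lv).area_km2)
                    for lv in config.homerange_levels]
            pd.DataFrame(rows, columns=["level", "area_km2"]).to_csv(
                out / "areas.csv", index=False, sep=config.delimiter)
            write_geojson(isopleth_geojson(ud, config.homerange_levels),
                          out / "isopleths.geojson")
            return {"h": bw.h, "areas": dict(rows), "n": pts.n}
        artifacts["homerange"] = stage("homerange")(_homerange)

    # --- statistics -----------------------------------------------------
    records = [j for j in journeys if j.departure.date and j.arrival.date]
    if records:
        recs = [JourneyRecord(j.individual, j.season, j.year,
                              j.departure.date, j.arrival.date,
                              j.n_stopovers, j.segment_lengths_km)
                for j in records]
        stage("stats")(lambda: write_stats_tables(recs, out,
                                                  delimiter=config.delimiter))
        artifacts["stats"] = str(out / "summary_stats.csv")

    write_geojson(tracks_to_geojson(kept_tracks), out / "tracks.geojson")
    (out / "summary.txt").write_text(
        "\n".join(provenance
                  + [f"tracks: {len(tracks)}",
                     f"journeys: {len(journeys)}"]) + "\n", encoding="utf-8")
    artifacts["summary"] = str(out / "summary.txt")
    return artifacts


# --------------------------------------------------------------------------
# statistics layer on a journey table (stats-only entry point)
# --------------------------------------------------------------------------

def fixture_statistics(journeys: list[JourneyRecord] | None = None) -> dict:
    """The full statistics battery on a journey table (default: the
    packaged reference journeys).

    Returns a flat dict: per-season distance summaries, the
    first/last-versus-middle and spring-versus-autumn segment t-tests,
    between-individual ANOVA F values (all individuals), repeatability
    ANOVA F and r (individuals with >= 2 round trips), the paired
    autumn/spring distance test, stopover means, and wintering
    residence durations.
    """
    js = journeys if journeys is not None else load_table1_fixture()
    aut = [j for j in js if j.season == "autumn"]
    spr = [j for j in js if j.season == "spring"]
    out: dict = {
        "n_autumn_journeys": len(aut),
        "n_spring_journeys": len(spr),
        "autumn_mean_total_km": float(np.mean([j.total_km for j in aut])),
        "autumn_sd_total_km": (float(np.std([j.total_km for j in aut], ddof=1))
                               if len(aut) > 1 else float("nan")),
        "spring_mean_total_km": float(np.mean([j.total_km for j in spr])),
        "autumn_mean_n_stopovers": float(np.mean([j.n_stopovers for j in aut])),
        "autumn_mean_duration_days": float(np.mean([j.duration_days for j in aut])),
        "autumn_max_duration_days": float(max(j.duration_days for j in aut)),
        "spring_mean_duration_days": float(np.mean([j.duration_days for j in spr])),
    }

    aut_segs = [s for j in aut for s in j.segment_lengths_km]
    spr_segs = [s for j in spr for s in j.segment_lengths_km]
    out["n_autumn_segments"] = len(aut_segs)
    out["n_spring_segments"] = len(spr_segs)
    out["autumn_segment_mean_km"] = float(np.mean(aut_segs))
    out["spring_segment_mean_km"] = float(np.mean(spr_segs))

    first_last, middle = segment_classes(js, "autumn")
    if len(first_last) >= 2 and len(middle) >= 2:
        out["first_last_mean_km"] = float(np.mean(first_last))
        out["middle_mean_km"] = float(np.mean(middle))
        tt = pooled_t_test(first_last, middle)
        out["t_first_last_vs_middle"] = tt.t
        out["df_first_last_vs_middle"] = tt.df
    if len(spr_segs) >= 2 and len(aut_segs) >= 2:
        tt = pooled_t_test(spr_segs, aut_segs)
        out["t_spring_vs_autumn_segments"] = tt.t
        out["df_spring_vs_autumn_segments"] = tt.df

    _, am, sm = paired_season_distances(js)
    if len(am) >= 2 and np.var(np.asarray(am) - np.asarray(sm)) > 0:
        tt = paired_t_test(am, sm)
        out["t_paired_autumn_spring_km"] = tt.t
        out["p_paired_autumn_spring_km"] = tt.p

    for var, key in (("departure_doy", "autumn_departure"),
                     ("arrival_doy", "winter_arrival"),
                     ("duration_days", "autumn_duration")):
        try:
            res = oneway_anova(journey_groups(js, var, "autumn"))
        except ValueError:
            continue
        out[f"F_{key}_all"] = res.F
        out[f"p_{key}_all"] = res.p

    repeaters = sorted(i for i, n in round_trip_counts(js).items() if n >= 2)
    out["repeat_individuals"] = repeaters
    for season, keys in (("autumn", ("autumn_departure", "winter_arrival",
                                     "autumn_duration")),
                         ("spring", ("spring_departure", "breeding_arrival",
                                     "spring_duration"))):
        for var, key in zip(("departure_doy", "arrival_doy", "duration_days"),
                            keys):
            try:
                rep = repeatability(journey_groups(js, var, season,
                                                   individuals=repeaters))
            except ValueError:
                continue
            out[f"F_{key}_repeat"] = rep.anova.F
            out[f"r_{key}_repeat"] = rep.r

    res_days = wintering_residences(js)
    out["n_wintering_seasons"] = len(res_days)
    if res_days:
        out["wintering_mean_days"] = float(np.mean(res_days))
        out["wintering_min_days"] = int(min(res_days))
        out["wintering_max_days"] = int(max(res_days))
    return out


def write_stats_tables(journeys: list[JourneyRecord], outdir: str | Path,
                       delimiter: str = ",") -> dict:
    """Emit the journey summary, ANOVA and repeatability tables as
    delimited text; returns the computed statistics dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stats = fixture_statistics(journeys)

    summarize_journeys(journeys).to_csv(out / "summary_stats.csv",
                                        index=False, sep=delimiter,
                                        float_format="%.3f")
    journeys_frame(journeys).to_csv(out / "journeys_table.csv", index=False,
                                    sep=delimiter)

    rows = []
    for var, key in (("departure_doy", "autumn_departure"),
                     ("arrival_doy", "winter_arrival"),
                     ("duration_days", "autumn_duration")):
        try:
            res = oneway_anova(journey_groups(journeys, var, "autumn"))
        except ValueError:
            continue
        rows.append((key, f"{res.df_between}, {res.df_within}",
                     round(res.F, 2), format_p(res.p)))
    pd.DataFrame(rows, columns=["variable", "df", "F", "p"]).to_csv(
        out / "anova_table.csv", index=False, sep=delimiter)

    rows = []
    repeaters = sorted(i for i, n in round_trip_counts(journeys).items()
                       if n >= 2)
    if len(repeaters) >= 2:
        for var, key in (("departure_doy", "autumn_departure"),
                         ("arrival_doy", "winter_arrival"),
                         ("duration_days", "autumn_duration")):
            try:
                rep = repeatability(journey_groups(journeys, var, "autumn",
                                                   individuals=repeaters))
            except ValueError:
                continue
            rows.append((key, f"{rep.anova.df_between}, {rep.anova.df_within}",
                         round(rep.anova.F, 2), round(rep.r, 2),
                         format_p(rep.anova.p)))
    pd.DataFrame(rows, columns=["variable", "df", "F", "r", "p"]).to_csv(
        out / "repeatability_table.csv", index=False, sep=delimiter)
    return stats
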