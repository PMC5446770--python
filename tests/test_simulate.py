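import dataclasses
import datetime as dt

import numpy as np
import pytest

from relicttrack.segmentation import Journey, MigrationEvent, Stopover, detect_stopovers
from relicttrack.simulate import (GroundTruth, SimConfig, SimConfigError,
                                  TrackEstimate, TruthStopover,
                                  destination_point, evaluate_recovery,
                                  simulate_annual_track)
from relicttrack.track_io import haversine_km

UTC = dt.timezone.utc

NOISELESS = dict(outlier_rate=0.0, duty_off_hours=0.0,
                 lc_sigma_m={k: 1e-6 for k in "3210AB"},
                 residence_radius_km=0.5)


class TestSimulation:
    def test_same_seed_bitwise_identical(self):
        t1, g1 = simulate_annual_track(SimConfig(seed=5))
        t2, g2 = simulate_annual_track(SimConfig(seed=5))
        assert np.array_equal(t1.t, t2.t)
        assert np.array_equal(t1.lat, t2.lat)
        assert np.array_equal(t1.lon, t2.lon)
        assert list(t1.lc) == list(t2.lc)
        assert np.array_equal(g1.outlier_mask, g2.outlier_mask)
        assert g1.autumn_departure == g2.autumn_departure

    def test_different_seed_differs(self):
        t1, _ = simulate_annual_track(SimConfig(seed=5))
        t2, _ = simulate_annual_track(SimConfig(seed=6))
        assert not np.array_equal(t1.lat, t2.lat)

    def test_noiseless_stopover_recovery(self):
        cfg = SimConfig(seed=2, **NOISELESS)
        track, truth = simulate_annual_track(cfg)
        stops = detect_stopovers(track)
        aut = [s for s in stops
               if truth.autumn_departure.timestamp() < s.start.timestamp()
               and s.end.timestamp() < truth.autumn_arrival.timestamp() + 60]
        assert len(aut) == truth.stopover_count("autumn")

    def test_duty_cycle_gap_structure(self):
        # fixes are hourly within on-windows; gaps between windows span
        # at least the off period
        cfg = SimConfig(seed=1)
        track, _ = simulate_annual_track(cfg)
        gaps = np.diff(track.t) / 3600.0
        inside = gaps <= cfg.sample_interval_hours + 1e-9
        between = gaps >= cfg.duty_off_hours - cfg.sample_interval_hours
        assert np.all(inside | between)
        # and the on-window runs never exceed the on period
        run = 0.0
        for gv in gaps:
            run = run + gv if gv <= 1.0 + 1e-9 else 0.0
            assert run <= cfg.duty_on_hours

    def test_lc_error_scales(self):
        # during a dispersal-free winter residence with negligible bird
        # movement, fix displacement from the site is pure LC error:
        # per-class RMS displacement must match the configured sigma
        cfg = dataclasses.replace(
            SimConfig(seed=0), residence_radius_km=1e-4, outlier_rate=0.0,
            winter_dispersal_prob=0.0, prebreeding_prob=0.0,
            duty_on_hours=23.0, duty_off_hours=1.0)
        disp: dict[str, list] = {}
        for seed in range(3):
            track, truth = simulate_annual_track(
                dataclasses.replace(cfg, seed=seed))
            t0 = truth.autumn_arrival.timestamp() + 86400.0
            t1 = truth.spring_departure.timestamp() - 86400.0
            mask = (track.t > t0) & (track.t < t1)
            for lat, lon, lc in zip(track.lat[mask], track.lon[mask],
                                    track.lc[mask]):
                disp.setdefault(lc, []).append(
                    haversine_km((lat, lon), cfg.winter_site_a) * 1000.0)
        assert sum(len(v) for v in disp.values()) >= 10_000
        for lc, vals in disp.items():
            rms = float(np.sqrt(np.mean(np.square(vals))))
            assert rms == pytest.approx(cfg.lc_sigma_m[lc], rel=0.10), lc

    def test_outliers_flagged_and_displaced(self):
        cfg = SimConfig(seed=4)
        track, truth = simulate_annual_track(cfg)
        frac = truth.outlier_mask.mean()
        assert 0.5 * cfg.outlier_rate <= frac <= 2.0 * cfg.outlier_rate
        # outliers are auxiliary-class by construction
        assert set(track.lc[truth.outlier_mask]) <= {"0", "A", "B"}

    def test_stopover_count_distribution(self):
        cfg = SimConfig()
        counts = []
        for seed in range(100):
            _, truth = simulate_annual_track(
                dataclasses.replace(cfg, seed=seed))
            counts.append(truth.stopover_count("autumn"))
        probs = np.asarray(cfg.n_stopovers_probs_autumn)
        mean = float(np.dot(np.arange(6), probs))
        var = float(np.dot(np.arange(6) ** 2, probs)) - mean ** 2
        se = (var / 100) ** 0.5
        assert abs(np.mean(counts) - mean) <= 3 * se

    def test_infeasible_config_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(flight_speed_kmh=0.0)
        with pytest.raises(SimConfigError):
            SimConfig(n_stopovers_probs_autumn=(0.5, 0.1, 0, 0, 0, 0))

    def test_destination_point_roundtrip(self):
        origin = (39.138, 109.870)
        for bearing, km in ((0, 204), (270, 100), (45, 540)):
            dest = destination_point(origin, bearing, km)
            assert haversine_km(origin, dest) == pytest.approx(km, rel=1e-6)


def _journey(season, dep, arr, stopovers):
    return Journey("S000", season, dep.year,
                   MigrationEvent(dep, 0.5), MigrationEvent(arr, 0.5),
                   tuple(stopovers), tuple([100.0] * (len(stopovers) + 1)))


def _stop(lat, lon, d0, d1):
    start = dt.datetime(2011, 8, d0, tzinfo=UTC)
    end = dt.datetime(2011, 8, d1, tzinfo=UTC)
    return Stopover((lat, lon), start, end, (end - start).days, 10)


class TestEvaluateRecovery:
    def _truth(self, stopovers):
        return GroundTruth(
            animal_id="S000",
            fix_times=np.array([0.0, 1.0, 2.0]),
            outlier_mask=np.array([False, False, True]),
            autumn_departure=dt.datetime(2011, 8, 1, 12, tzinfo=UTC),
            autumn_arrival=dt.datetime(2011, 8, 20, 12, tzinfo=UTC),
            spring_departure=dt.datetime(2012, 4, 5, tzinfo=UTC),
            spring_arrival=dt.datetime(2012, 4, 9, tzinfo=UTC),
            stopovers=stopovers, winter_events=[], prebreeding=None)

    def test_perfect_estimate_scores_perfectly(self):
        truth_stops = [TruthStopover("autumn", (41.0, 113.0),
                                     dt.datetime(2011, 8, 5, tzinfo=UTC),
                                     dt.datetime(2011, 8, 10, tzinfo=UTC))]
        est_stops = [_stop(41.0, 113.0, 5, 10)]
        est = TrackEstimate("S000", [
            _journey("autumn", dt.date(2011, 8, 1), dt.date(2011, 8, 20),
                     est_stops)], est_stops, [])
        rep = evaluate_recovery([est], [self._truth(truth_stops)])
        assert rep.departure_mae_days == 0.0
        assert rep.arrival_mae_days == 0.0
        assert rep.stopover_count_accuracy == 1.0
        assert rep.stopover_precision == 1.0 and rep.stopover_recall == 1.0
        assert rep.outlier_recall == 0.0          # outlier never removed
        assert rep.false_removal_rate == 0.0

    def test_spurious_stopover_counts_against_precision(self):
        truth_stops = [
            TruthStopover("autumn", (41.0, 113.0),
                          dt.datetime(2011, 8, 5, tzinfo=UTC),
                          dt.datetime(2011, 8, 8, tzinfo=UTC)),
            TruthStopover("autumn", (41.3, 114.5),
                          dt.datetime(2011, 8, 10, tzinfo=UTC),
                          dt.datetime(2011, 8, 14, tzinfo=UTC))]
        est_stops = [_stop(41.0, 113.0, 5, 8), _stop(41.3, 114.5, 10, 14),
                     _stop(40.0, 111.0, 16, 18)]
        est = TrackEstimate("S000", [
            _journey("autumn", dt.date(2011, 8, 1), dt.date(2011, 8, 20),
                     est_stops)], est_stops, [])
        rep = evaluate_recovery([est], [self._truth(truth_stops)])
        assert rep.stopover_precision == pytest.approx(2 / 3)
        assert rep.stopover_recall == 1.0
        assert rep.stopover_count_accuracy == 0.0

    def test_id_mismatch_rejected(self):
        est = TrackEstimate("WRONG", [], [], [])
        with pytest.raises(ValueError):
            evaluate_recovery([est], [self._truth([])])
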