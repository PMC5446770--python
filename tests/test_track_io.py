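import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relicttrack import track_io
from relicttrack.track_io import (ArgosFix, FixtureIntegrityError, ReadReport,
                                  SchemaError, Track, day_of_year_nonleap,
                                  date_from_nonleap_doy, haversine_km,
                                  load_table1_fixture, load_table4_sites,
                                  nonleap_days_between, read_fixes,
                                  write_fixes)
from relicttrack.phenology import round_trip_counts

UTC = dt.timezone.utc


def _write(tmp_path, text, name="fixes.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


WELL_FORMED = (
    "animal_id,timestamp,lat,lon,lc\n"
    "G3,2008-08-01T06:00:00+00:00,39.1,109.9,3\n"
    "G3,2008-08-01T07:00:00+00:00,39.2,110.1,B\n"
    "G3,2008-08-01T08:00:00+00:00,39.3,110.4,1\n"
)


class TestReadFixes:
    def test_identity_read(self, tmp_path):
        tracks = read_fixes(_write(tmp_path, WELL_FORMED))
        assert len(tracks) == 1
        assert tracks[0].animal_id == "G3"
        assert len(tracks[0]) == 3
        assert list(tracks[0].lc) == ["3", "B", "1"]

    def test_bad_lc_row_rejected(self, tmp_path):
        text = WELL_FORMED.replace("110.1,B", "110.1,X")
        rep = ReadReport()
        tracks = read_fixes(_write(tmp_path, text), report=rep)
        assert len(tracks[0]) == 2
        assert rep.n_rejected == 1 and rep.reasons["lc"] == 1

    def test_unsorted_rows_sorted(self, tmp_path, rng):
        lines = WELL_FORMED.splitlines()
        shuffled = [lines[0]] + [lines[i] for i in rng.permutation([1, 2, 3])]
        tracks = read_fixes(_write(tmp_path, "\n".join(shuffled) + "\n"))
        assert np.all(np.diff(tracks[0].t) > 0)

    def test_missing_column_schema_error(self, tmp_path):
        text = WELL_FORMED.replace("lc", "klass")
        with pytest.raises(SchemaError):
            read_fixes(_write(tmp_path, text))

    def test_dialect_mapping(self, tmp_path):
        text = WELL_FORMED.replace("animal_id", "bird")
        tracks = read_fixes(_write(tmp_path, text),
                            dialect={"animal_id": "bird"})
        assert tracks[0].animal_id == "G3"

    def test_write_read_roundtrip(self, tmp_path):
        tracks = read_fixes(_write(tmp_path, WELL_FORMED))
        out = tmp_path / "out.csv"
        write_fixes(tracks, out)
        back = read_fixes(out)
        assert np.array_equal(back[0].t, tracks[0].t)
        assert np.array_equal(back[0].lat, tracks[0].lat)
        assert np.array_equal(back[0].lon, tracks[0].lon)
        assert list(back[0].lc) == list(tracks[0].lc)


class TestArgosFix:
    def test_validation(self):
        ts = dt.datetime(2010, 1, 1, tzinfo=UTC)
        with pytest.raises(ValueError):
            ArgosFix("a", ts, 91.0, 0.0, "3")
        with pytest.raises(ValueError):
            ArgosFix("a", ts, 0.0, 181.0, "3")
        with pytest.raises(ValueError):
            ArgosFix("a", ts, 0.0, 0.0, "X")

    def test_naive_timestamp_becomes_utc(self):
        fix = ArgosFix("a", dt.datetime(2010, 1, 1, 12), 0.0, 0.0, "3")
        assert fix.timestamp.tzinfo == UTC

    def test_track_rejects_decreasing_times(self):
        with pytest.raises(ValueError):
            Track("a", np.array([2.0, 1.0]), np.zeros(2), np.zeros(2),
                  np.array(["3", "3"], dtype=object))


class TestHaversine:
    def test_identity_is_zero(self):
        assert haversine_km((39.0, 110.0), (39.0, 110.0)) == 0.0

    def test_one_degree_equator(self):
        # one degree of arc = 6371 * pi / 180
        assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(
            6371.0 * math.pi / 180.0, rel=1e-9)

    def test_against_law_of_cosines(self):
        a, b = (39.138, 109.870), (41.462, 113.901)
        p1, p2 = math.radians(a[0]), math.radians(b[0])
        dl = math.radians(b[1] - a[1])
        oracle = 6371.0 * math.acos(
            math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl))
        assert haversine_km(a, b) == pytest.approx(oracle, rel=1e-9)
        assert haversine_km(a, b) == pytest.approx(428.0, abs=1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_km((95.0, 0.0), (0.0, 0.0))

    def test_triangle_inequality(self, rng):
        lat = rng.uniform(-89, 89, size=(1000, 3))
        lon = rng.uniform(-179, 179, size=(1000, 3))
        for k in range(1000):
            a, b, c = [(lat[k, i], lon[k, i]) for i in range(3)]
            assert haversine_km(a, c) <= (haversine_km(a, b)
                                          + haversine_km(b, c) + 1e-9)

    @given(st.floats(-89, 89), st.floats(-179, 179),
           st.floats(-89, 89), st.floats(-179, 179))
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_nonnegative(self, la1, lo1, la2, lo2):
        d1 = haversine_km((la1, lo1), (la2, lo2))
        d2 = haversine_km((la2, lo2), (la1, lo1))
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert d1 >= 0.0


class TestNonLeapCalendar:
    @pytest.mark.parametrize("date,doy", [
        (dt.date(2008, 1, 1), 1),
        (dt.date(2008, 8, 3), 215),     # 31+28+31+30+31+30+31+3
        (dt.date(2010, 9, 11), 254),
        (dt.date(2008, 2, 29), 59),     # collapses onto Feb 28
        (dt.date(2011, 12, 31), 365),
    ])
    def test_day_of_year(self, date, doy):
        assert day_of_year_nonleap(date) == doy

    def test_inverse_roundtrip(self):
        for doy in range(1, 366):
            assert day_of_year_nonleap(date_from_nonleap_doy(doy)) == doy

    def test_cross_year_duration(self):
        # (365 - doy_start) + doy_end
        assert nonleap_days_between(dt.date(2010, 9, 11),
                                    dt.date(2011, 4, 5)) == 206

    def test_within_year_duration(self):
        assert nonleap_days_between(dt.date(2008, 7, 26),
                                    dt.date(2008, 9, 1)) == 37


class TestReferenceFixture:
    def test_journey_counts(self, journeys):
        assert sum(j.season == "autumn" for j in journeys) == 20
        assert sum(j.season == "spring" for j in journeys) == 13

    def test_single_journey_row(self, journeys):
        j = [x for x in journeys
             if x.individual == "G5" and x.season == "autumn"
             and x.year == 2011][0]
        assert j.departure == dt.date(2011, 7, 27)
        assert j.arrival == dt.date(2011, 7, 28)
        assert j.n_stopovers == 0
        assert j.segment_lengths_km == (670.0,)

    def test_totals(self, journeys):
        aut = [j for j in journeys if j.season == "autumn"]
        spr = [j for j in journeys if j.season == "spring"]
        assert sum(s for j in aut for s in j.segment_lengths_km) == 16780
        assert sum(len(j.segment_lengths_km) for j in aut) == 48
        assert sum(len(j.segment_lengths_km) for j in spr) == 16

    def test_round_trips_per_individual(self, journeys):
        counts = sorted(n for n in round_trip_counts(journeys).values() if n)
        assert counts == [1, 2, 2, 4, 4]

    def test_checksum_guard(self, monkeypatch):
        monkeypatch.setattr(track_io, "_TABLE1_SHA256", "0" * 64)
        with pytest.raises(FixtureIntegrityError):
            load_table1_fixture()

    def test_site_table(self):
        sites = load_table4_sites()
        aut = sites[sites.season == "autumn"]
        assert len(sites) == 16
        assert aut.accumulated_days.sum() == 228
        top3 = aut.nlargest(3, "accumulated_days").accumulated_days.sum()
        assert top3 == 151                       # 66.2% of the autumn total
        assert top3 / aut.accumulated_days.sum() == pytest.approx(0.662, abs=0.001)
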