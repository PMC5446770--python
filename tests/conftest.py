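import datetime as dt

import numpy as np
import pytest

from relicttrack.track_io import Track, load_table1_fixture

UTC = dt.timezone.utc


def make_track(points, animal_id="T1", start=None, lc="B"):
    """Build a Track from (hours_offset, lat, lon[, lc]) tuples."""
    start = start or dt.datetime(2011, 7, 1, tzinfo=UTC)
    t0 = start.timestamp()
    t, lat, lon, lcs = [], [], [], []
    for p in points:
        t.append(t0 + p[0] * 3600.0)
        lat.append(p[1])
        lon.append(p[2])
        lcs.append(p[3] if len(p) > 3 else lc)
    return Track(animal_id, np.array(t), np.array(lat), np.array(lon),
                 np.array(lcs, dtype=object))


@pytest.fixture(scope="session")
def journeys():
    """The packaged reference journey table."""
    return load_table1_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
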