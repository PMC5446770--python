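import math

import numpy as np
import pytest
from scipy import stats as sps

from relicttrack.phenology import (DegenerateDataError, GroupedObservations,
                                   journey_groups, oneway_anova,
                                   paired_season_distances, paired_t_test,
                                   pooled_t_test, repeatability,
                                   round_trip_counts, segment_classes,
                                   summarize_journeys, wintering_residences)

REPEATERS = ["G11", "G4", "G5", "G7"]


def g(*groups):
    return GroupedObservations({f"g{i}": list(v) for i, v in enumerate(groups)})


class TestOnewayAnova:
    def test_hand_decomposition(self):
        # SSB = 13.5, MSW = 1 -> F = 13.5 on (1, 4)
        res = oneway_anova(g([1, 2, 3], [4, 5, 6]))
        assert res.F == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.ms_within == pytest.approx(1.0)

    def test_agrees_with_scipy(self, rng):
        groups = [rng.normal(size=n) for n in (4, 7, 5)]
        res = oneway_anova(g(*groups))
        F, p = sps.f_oneway(*groups)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_equal_means_zero_f(self):
        res = oneway_anova(g([-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0]))
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            oneway_anova(g([1.0, 1.0], [2.0, 2.0]))

    def test_affine_invariance(self, rng):
        groups = [list(rng.normal(size=n)) for n in (3, 5, 4)]
        f0 = oneway_anova(g(*groups)).F
        shifted = [[7.0 + 3.0 * v for v in grp] for grp in groups]
        assert oneway_anova(g(*shifted)).F == pytest.approx(f0, rel=1e-9)

    def test_group_validation(self):
        with pytest.raises(ValueError):
            GroupedObservations({"a": [1.0]})
        with pytest.raises(ValueError):
            GroupedObservations({"a": [1.0], "b": []})
        with pytest.raises(ValueError):
            GroupedObservations({"a": [1.0], "b": [2.0]})   # N == a


class TestRepeatability:
    def test_formula_arithmetic(self):
        # n0 = 3, s2_among = 12.5/3, r = (12.5/3) / (12.5/3 + 1)
        rep = repeatability(g([1, 2, 3], [4, 5, 6]))
        assert rep.n0 == pytest.approx(3.0)
        assert rep.r == pytest.approx((12.5 / 3) / (12.5 / 3 + 1))
        assert rep.r == pytest.approx(0.806, abs=5e-4)

    def test_negative_r_unclamped(self):
        rep = repeatability(g([1.0, 4.0, 2.0], [2.0, 1.0, 4.0]))
        assert rep.anova.ms_between < rep.anova.ms_within
        assert rep.r < 0.0

    def test_affine_invariance(self, rng):
        groups = [list(rng.normal(size=n)) for n in (4, 3, 5)]
        r0 = repeatability(g(*groups)).r
        shifted = [[-2.0 + 0.5 * v for v in grp] for grp in groups]
        assert repeatability(g(*shifted)).r == pytest.approx(r0, rel=1e-9)


class TestTTests:
    def test_pooled_hand_example(self):
        # sp^2 = 1, se = sqrt(2/3) -> t = -3 / sqrt(2/3)
        res = pooled_t_test([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), rel=1e-9)
        assert res.df == 4

    def test_identical_samples_zero_t(self):
        res = pooled_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            pooled_t_test([1.0, 1.0], [2.0, 2.0])

    def test_paired_symmetric_differences(self):
        res = paired_t_test([1.0, 3.0], [2.0, 2.0])   # diffs {-1, +1}
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_paired_pairs_form(self):
        # diffs {1, 2, 3}: mean 2, sd 1 -> t = 2 * sqrt(3)
        res = paired_t_test([(2, 1), (4, 2), (6, 3)])
        assert res.t == pytest.approx(2.0 * math.sqrt(3.0), rel=1e-9)
        assert res.df == 2

    def test_paired_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t_test([2.0, 3.0], [1.0, 2.0])     # diffs all 1
        res = paired_t_test([1.0, 2.0], [1.0, 2.0])   # diffs all 0
        assert res.t == 0.0


class TestReferenceJourneyStatistics:
    """The statistics battery on the packaged reference journey table,
    non-leap day-of-year convention throughout."""

    def test_anova_all_individuals(self, journeys):
        cases = {"departure_doy": 6.20, "duration_days": 7.72}
        for var, expected in cases.items():
            res = oneway_anova(journey_groups(journeys, var, "autumn"))
            assert (res.df_between, res.df_within) == (8, 11)
            assert res.F == pytest.approx(expected, abs=0.01)

    def test_anova_repeat_individuals(self, journeys):
        assert sorted(i for i, n in round_trip_counts(journeys).items()
                      if n >= 2) == REPEATERS
        cases = {"arrival_doy": 17.42, "duration_days": 14.28,
                 "departure_doy": 1.60}
        for var, expected in cases.items():
            rep = repeatability(journey_groups(journeys, var, "autumn",
                                               individuals=REPEATERS))
            assert (rep.anova.df_between, rep.anova.df_within) == (3, 10)
            assert rep.anova.F == pytest.approx(expected, abs=0.01)

    def test_repeatability_values_reported(self, journeys):
        # printed r (0.80, 0.76) differs slightly from the Lessells-Boag
        # formula on these data; the coefficients are reported, F asserted
        rep = repeatability(journey_groups(journeys, "arrival_doy", "autumn",
                                           individuals=REPEATERS))
        assert 0.75 <= rep.r <= 0.9
        assert rep.n0 == pytest.approx((14 - 54 / 14) / 3)

    def test_segment_t_tests(self, journeys):
        first_last, middle = segment_classes(journeys, "autumn")
        assert (len(first_last), len(middle)) == (18, 14)
        assert round(float(np.mean(first_last))) == 401
        assert round(float(np.mean(middle))) == 66
        res = pooled_t_test(first_last, middle)
        assert res.t == pytest.approx(16.13, abs=0.01) and res.df == 30

        aut = [s for j in journeys if j.season == "autumn"
               for s in j.segment_lengths_km]
        spr = [s for j in journeys if j.season == "spring"
               for s in j.segment_lengths_km]
        res = pooled_t_test(spr, aut)
        assert res.t == pytest.approx(4.136, abs=0.001) and res.df == 62

    def test_paired_distance_test(self, journeys):
        inds, am, sm = paired_season_distances(journeys)
        assert len(inds) == 5
        diffs = sorted(round(a - s, 1) for a, s in zip(am, sm))
        assert diffs == [-80.0, 0.0, 10.0, 207.5, 230.0]
        res = paired_t_test(am, sm)
        assert res.df == 4
        assert res.t == pytest.approx(1.20, abs=0.01)

    def test_wintering_residences(self, journeys):
        days = wintering_residences(journeys)
        assert len(days) == 13
        assert min(days) == 206
        assert round(float(np.mean(days))) == 234

    def test_summaries(self, journeys):
        table = summarize_journeys(journeys)
        aut = table[table.season == "autumn"].set_index("variable")
        assert aut.loc["duration_days", "max"] == 42
        assert aut.loc["total_km", "mean"] == pytest.approx(839.0)
        assert aut.loc["n_stopovers", "mean"] == pytest.approx(1.4)
        assert aut.loc["departure_doy", "mean_date"] == "31 Jul"
        spr = table[table.season == "spring"].set_index("variable")
        assert spr.loc["total_km", "mean"] == pytest.approx(737.7, abs=0.05)

    def test_single_journey_sd_undefined(self, journeys):
        one = [j for j in journeys if j.individual == "G6"]
        table = summarize_journeys(one)
        assert np.isnan(table.sd).all()
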